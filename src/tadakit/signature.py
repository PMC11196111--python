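"""Rank-based gene-signature enrichment for single cells (AUCell-style).

Each cell's genes are ranked by decreasing expression and the score is the
area under the recovery curve of signature genes within the top fraction of
the ranking, normalised to [0, 1] by the maximum attainable area for that
signature size.  Being rank-based, the score is invariant to any monotone
transformation of a cell's expression values.  Expression matrices are plain
genes x cells DataFrames (genes as index), with an optional per-cell cluster
label Series.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("tadakit")


@dataclass
class GeneSignature:
    genes: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        uniq = []
        for g in self.genes:
            if g not in seen:
                uniq.append(g)
                seen.add(g)
        self.genes = uniq
        if not self.genes:
            raise ValueError("empty gene signature")


def make_signature(gene_table: pd.DataFrame, n: int = 500,
                   provenance: str = "tada-top") -> GeneSignature:
    """Top-n genes by ascending q, ties by descending |log2FC|, then by id.

    ``gene_table`` must carry gene_id, q and log2fc columns (the output of
    the differential-occupancy gene table).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(gene_table):
        logger.warning(
            "requested %d signature genes but table has %d; using all",
            n, len(gene_table),
        )
    ranked = gene_table.assign(_abs=gene_table["log2fc"].abs()).sort_values(
        ["q", "_abs", "gene_id"], ascending=[True, False, True]
    )
    return GeneSignature(ranked["gene_id"].head(n).tolist(), provenance)


@dataclass
class AucScore:
    auc: pd.Series  # per cell, in [0, 1]
    top_frac: float
    threshold: float | None = None
    enriched: pd.Series | None = None  # bool per cell, set by threshold_enriched


def aucell_score(
    matrix: pd.DataFrame,
    signature: GeneSignature,
    top_frac: float = 0.05,
    tie_method: str = "average",
    rng: np.random.Generator | None = None,
) -> AucScore:
    """Per-cell area under the signature recovery curve.

    With G genes and K = ceil(top_frac * G), the recovery curve is
    R(k) = #{signature genes with rank <= k}, k = 1..K, where rank 1 is the
    cell's most highly expressed gene and ties (notably zeros) receive
    average ranks.  AUC = sum_k R(k) divided by the maximum attainable sum
    (all signature genes at the very top: R*(k) = min(k, |S|)).
    ``tie_method="random"`` reproduces randomised tie-breaking for
    cross-checks and needs ``rng``.
    """
    present = [g for g in signature.genes if g in matrix.index]
    missing = [g for g in signature.genes if g not in matrix.index]
    if missing:
        logger.warning("signature genes absent from matrix: %s", missing)
    if not present:
        raise ValueError("signature does not intersect matrix genes")
    G = matrix.shape[0]
    K = math.ceil(top_frac * G)
    max_area = sum(min(k, len(present)) for k in range(1, K + 1))
    in_sig = matrix.index.isin(present)
    values = matrix.to_numpy(dtype=float)
    aucs = np.empty(matrix.shape[1])
    for j in range(matrix.shape[1]):
        col = values[:, j]
        if tie_method == "random":
            if rng is None:
                raise ValueError("tie_method='random' requires rng")
            jitter = rng.random(G) * 1e-9
            ranks = rankdata(-(col + jitter), method="ordinal")
        else:
            ranks = rankdata(-col, method=tie_method)
        sig_ranks = ranks[in_sig]
        # R(k) summed over k=1..K equals, per signature gene, the number of
        # integer k in 1..K with k >= rank, i.e. K - ceil(rank) + 1 (average
        # ranks can be fractional).
        effective = np.ceil(sig_ranks)
        contrib = np.clip(K - effective + 1.0, 0.0, None)
        aucs[j] = contrib.sum() / max_area
    return AucScore(pd.Series(aucs, index=matrix.columns, name="auc"), top_frac)


def threshold_enriched(scores: AucScore, threshold: float = 0.196) -> pd.Series:
    """Flag cells with AUC strictly above the threshold.

    Returns the boolean per-cell Series and records it (with the threshold)
    on the score object.  The count and fraction are logged.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    enriched = scores.auc > threshold
    scores.threshold = threshold
    scores.enriched = enriched
    logger.info(
        "enriched cells: %d / %d (%.1f%%)",
        int(enriched.sum()), len(enriched), 100.0 * enriched.mean(),
    )
    return enriched


def cluster_expression_summary(
    matrix: pd.DataFrame,
    labels: pd.Series,
    genes: Sequence[str],
) -> pd.DataFrame:
    """Dot-plot statistics: per gene x cluster, fraction of positive cells
    (value > 0) and mean expression."""
    if not labels.index.equals(pd.Index(matrix.columns)):
        labels = labels.reindex(matrix.columns)
        if labels.isna().any():
            raise ValueError("labels do not cover all cells")
    rows = []
    for gene in genes:
        if gene not in matrix.index:
            logger.warning("gene %s not in matrix; skipped", gene)
            continue
        expr = matrix.loc[gene]
        for cluster, cells in expr.groupby(labels):
            rows.append(
                {
                    "gene": gene,
                    "cluster": cluster,
                    "frac_positive": float((cells > 0).mean()),
                    "mean_expression": float(cells.mean()),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "cluster", "frac_positive",
                                       "mean_expression"])


def coexpression_fraction(
    matrix: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    positive_threshold: float = 0.0,
) -> float:
    """Fraction of gene_a-positive cells that are also gene_b-positive.

    Positivity means expression strictly above ``positive_threshold``
    (default: any nonzero count).  If no cell is gene_a-positive the
    fraction is defined as 0 with a warning.
    """
    for g in (gene_a, gene_b):
        if g not in matrix.index:
            raise KeyError(f"gene {g!r} not in matrix")
    a_pos = matrix.loc[gene_a] > positive_threshold
    if not a_pos.any():
        logger.warning("no %s-positive cells; coexpression fraction set to 0", gene_a)
        return 0.0
    b_pos = matrix.loc[gene_b] > positive_threshold
    return float((a_pos & b_pos).sum() / a_pos.sum())


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x cells delimited matrix (gene ids in first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_matrix_mtx(
    mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> pd.DataFrame:
    """Read a matrix-market triplet with row (gene) and column (cell) id files."""
    from scipy.io import mmread

    m = mmread(str(mtx_path)).toarray()
    genes = [l.strip() for l in open(genes_path) if l.strip()]
    cells = [l.strip() for l in open(cells_path) if l.strip()]
    return pd.DataFrame(m, index=genes, columns=cells)
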