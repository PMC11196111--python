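"""Context-dependent multi-omics candidate filter.

A gene is nominated only when four independent lines of evidence agree:
it loses Pol II occupancy under the signaling perturbation (DamID "down"
set), it is transcriptionally up in the gain-of-function bulk contrast, down
in the loss-of-function contrast, and it is expressed in receptor-positive
cells in the single-cell data.  Every criterion leaves an audit flag per
gene, so the reason a gene falls out of the intersection is always
recoverable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .signature import coexpression_fraction

logger = logging.getLogger("tadakit")


@dataclass
class FilterParams:
    """Thresholds of the four-way intersection filter."""

    gof_min_log2fc: float = 1.5     # bulk gain-of-function: log2FC > this
    lof_max_log2fc: float = -1.5    # bulk loss-of-function: log2FC < this
    bulk_max_p: float = 0.05
    coexpression_min_fraction: float = 0.1
    positive_threshold: float = 0.0
    use_adjusted_p: bool = False    # read a 'q' column instead of 'p'

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _check_de_table(table: pd.DataFrame, name: str) -> pd.DataFrame:
    required = {"gene_id", "log2fc"}
    if not required <= set(table.columns):
        raise ValueError(f"{name} table must have columns {sorted(required)}")
    if table["gene_id"].duplicated().any():
        raise ValueError(f"{name} table has duplicate gene ids")
    return table.set_index("gene_id")


def context_filter(
    tada_down: Iterable[str],
    de_gof: pd.DataFrame,
    de_lof: pd.DataFrame,
    matrix: pd.DataFrame,
    alk_gene: str = "Alk",
    params: FilterParams | None = None,
    cluster_labels: pd.Series | None = None,
    coexpression_mode: str = "fraction",
) -> pd.DataFrame:
    """Intersect the four evidence streams over all genes seen anywhere.

    Returns one row per gene with boolean columns tada/gof/lof/coexpr and
    an overall ``candidate`` flag that is True iff all four pass.  Genes
    absent from a bulk table fail that criterion (recorded as absent).
    ``coexpression_mode="cluster"`` instead requires the gene's positive
    cells to share a cluster with the receptor-positive cells'
    majority cluster (requires ``cluster_labels``).
    """
    params = params or FilterParams()
    if de_gof is None or de_lof is None:
        raise ValueError("both GOF and LOF contrast tables are required")
    gof = _check_de_table(de_gof, "GOF")
    lof = _check_de_table(de_lof, "LOF")
    pcol = "q" if params.use_adjusted_p else "p"
    for name, tbl in (("GOF", gof), ("LOF", lof)):
        if pcol not in tbl.columns:
            raise ValueError(f"{name} table lacks a {pcol!r} column")
    tada_down = set(tada_down)
    universe = sorted(tada_down | set(gof.index) | set(lof.index))

    if coexpression_mode == "cluster":
        if cluster_labels is None:
            raise ValueError("cluster mode requires cluster_labels")
        alk_pos = matrix.loc[alk_gene] > params.positive_threshold
        alk_clusters = set(cluster_labels[alk_pos.reindex(cluster_labels.index,
                                                          fill_value=False)])

    rows = []
    for gene in universe:
        in_tada = gene in tada_down
        if gene in gof.index:
            g = gof.loc[gene]
            gof_pass = bool(
                g["log2fc"] > params.gof_min_log2fc and g[pcol] <= params.bulk_max_p
            )
            gof_status = "pass" if gof_pass else "fail"
        else:
            gof_pass, gof_status = False, "absent"
        if gene in lof.index:
            l = lof.loc[gene]
            lof_pass = bool(
                l["log2fc"] < params.lof_max_log2fc and l[pcol] <= params.bulk_max_p
            )
            lof_status = "pass" if lof_pass else "fail"
        else:
            lof_pass, lof_status = False, "absent"
        if gene in matrix.index:
            if coexpression_mode == "fraction":
                frac = coexpression_fraction(
                    matrix, alk_gene, gene,
                    positive_threshold=params.positive_threshold,
                )
                co_pass = frac >= params.coexpression_min_fraction
            elif coexpression_mode == "cluster":
                pos = matrix.loc[gene] > params.positive_threshold
                gene_clusters = set(cluster_labels[pos.reindex(
                    cluster_labels.index, fill_value=False)])
                frac = np.nan
                co_pass = bool(gene_clusters & alk_clusters)
            else:
                raise ValueError(f"unknown coexpression mode {coexpression_mode!r}")
            co_status = "pass" if co_pass else "fail"
        else:
            frac, co_pass, co_status = np.nan, False, "absent"
        rows.append(
            {
                "gene_id": gene,
                "tada": in_tada,
                "gof": gof_pass,
                "gof_status": gof_status,
                "lof": lof_pass,
                "lof_status": lof_status,
                "coexpr": co_pass,
                "coexpr_status": co_status,
                "coexpr_fraction": frac,
                "candidate": in_tada and gof_pass and lof_pass and co_pass,
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    out.attrs["params"] = params.to_dict()
    logger.info("context filter: %d candidates of %d genes",
                int(out["candidate"].sum()), len(out))
    return out


def set_overlap(a: Iterable[str], b: Iterable[str]) -> dict:
    """Exact set arithmetic between two gene sets, with a membership table."""
    a, b = set(a), set(b)
    inter = a & b
    table = pd.DataFrame(
        {
            "gene_id": sorted(a | b),
        }
    )
    table["in_a"] = table["gene_id"].isin(a)
    table["in_b"] = table["gene_id"].isin(b)
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
        "intersection": sorted(inter),
        "table": table,
    }


def write_candidates(table: pd.DataFrame, path) -> None:
    """Write the audit table as TSV with the parameter record in # header lines."""
    with open(path, "w") as fh:
        params = table.attrs.get("params", {})
        fh.write("# params " + json.dumps(params, sort_keys=True) + "\n")
        table.to_csv(fh, sep="\t")
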