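"""Differential Pol II occupancy from DamID fragment counts.

The quantification chain mirrors the standard window-based differential
binding workflow: reads are counted onto GATC fragments, normalised to
log2-CPM, tested per fragment with a moderated two-sample t statistic,
clustered into peaks by genomic proximity (gap tolerance with a maximum peak
width), combined with the Simes rule, and FDR-filtered across peaks with
Benjamini-Hochberg.  The contrast convention is log2FC = perturbation minus
control, so loci that lose occupancy under the perturbation carry negative
log2FC and are selected with direction="down".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .gatc import GatcFragmentMap

logger = logging.getLogger("tadakit")

# Feature-annotation categories in priority order (highest first).
FEATURE_PRIORITY = [
    "Promoter (<=1kb)",
    "Promoter (1-2kb)",
    "Promoter (2-3kb)",
    "5' UTR",
    "3' UTR",
    "Exon",
    "Intron",
    "Downstream (<=3kb)",
    "Distal Intergenic",
]


@dataclass
class GeneModel:
    """Minimal gene annotation: span, strand, TSS and exon/UTR structure."""

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    start: int  # span start, 0-based
    end: int  # span end, exclusive
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene/exon/UTR features from a 9-column GFF3 file.

    Only the standard columns are interpreted; the ID/Parent attributes link
    exons and UTRs to their gene.  GFF3 is 1-based inclusive; converted to
    0-based half-open here.
    """
    genes: dict[str, GeneModel] = {}
    children: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _, ftype, start, end, _, strand, _, attrs = f
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            s, e = int(start) - 1, int(end)
            if ftype == "gene":
                gid = attr.get("ID", attr.get("gene_id", ""))
                genes[gid] = GeneModel(gid, contig, strand, s, e)
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                parent = attr.get("Parent", "")
                children.append((parent, ftype, s, e))
    for parent, ftype, s, e in children:
        gene = genes.get(parent)
        if gene is None:
            continue
        if ftype == "exon":
            gene.exons.append((s, e))
        elif ftype == "five_prime_UTR":
            gene.utr5.append((s, e))
        else:
            gene.utr3.append((s, e))
    for g in genes.values():
        g.exons.sort()
        g.utr5.sort()
        g.utr3.sort()
    return list(genes.values())


def fragments_frame(fragment_map: GatcFragmentMap) -> pd.DataFrame:
    """Flatten a fragment map into a DataFrame with a stable fragment_id index."""
    rows = []
    for contig, frags in fragment_map.fragments.items():
        for start, end in frags:
            rows.append((contig, int(start), int(end)))
    df = pd.DataFrame(rows, columns=["contig", "start", "end"])
    df.index.name = "fragment_id"
    return df


@dataclass
class FragmentCountMatrix:
    """Read counts per GATC fragment (rows) and sample (columns)."""

    fragments: pd.DataFrame  # contig/start/end per fragment_id
    counts: pd.DataFrame  # fragment_id x sample, int
    conditions: dict[str, str]  # sample -> condition label
    dropped: dict[str, int]  # sample -> reads not assignable to any fragment

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read BED3+ intervals into a (contig, start, end) frame."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2])))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def count_reads_per_fragment(
    reads_by_sample: Mapping[str, pd.DataFrame | str | Path],
    fragment_map: GatcFragmentMap,
    conditions: Mapping[str, str],
) -> FragmentCountMatrix:
    """Assign each read to the fragment containing its midpoint.

    Midpoint containment in half-open fragments gives every read a unique
    bin; a midpoint falling exactly on a cut boundary belongs to the fragment
    starting there.  Reads whose midpoint lies outside all fragments (or on
    an unknown contig) are dropped and tallied per sample.
    """
    for sample in reads_by_sample:
        if sample not in conditions:
            raise ValueError(f"sample {sample!r} has no condition label")
    frag_df = fragments_frame(fragment_map)
    # per-contig lookup arrays
    lookup: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for contig, grp in frag_df.groupby("contig", sort=False):
        order = np.argsort(grp["start"].to_numpy())
        lookup[contig] = (
            grp["start"].to_numpy()[order],
            grp["end"].to_numpy()[order],
            grp.index.to_numpy()[order],
        )
    counts = pd.DataFrame(
        0, index=frag_df.index, columns=list(reads_by_sample), dtype=int
    )
    dropped: dict[str, int] = {}
    for sample, reads in reads_by_sample.items():
        if not isinstance(reads, pd.DataFrame):
            reads = read_bed_intervals(reads)
        n_drop = 0
        for contig, grp in reads.groupby("contig", sort=False):
            if contig not in lookup:
                n_drop += len(grp)
                continue
            starts, ends, ids = lookup[contig]
            mids = (grp["start"].to_numpy() + grp["end"].to_numpy()) / 2.0
            idx = np.searchsorted(starts, mids, side="right") - 1
            ok = (idx >= 0) & (mids < ends[np.clip(idx, 0, len(ends) - 1)])
            n_drop += int((~ok).sum())
            hit_ids = ids[idx[ok]]
            if len(hit_ids):
                add = np.bincount(
                    hit_ids, minlength=len(frag_df)
                )
                counts[sample] += add
        dropped[sample] = n_drop
        if n_drop:
            logger.info("sample %s: %d reads outside fragments", sample, n_drop)
    return FragmentCountMatrix(frag_df, counts, dict(conditions), dropped)


def normalize_log2(
    matrix: FragmentCountMatrix, pseudocount: float = 0.5
) -> pd.DataFrame:
    """log2-CPM with pseudocount: log2((count + pc) / library_size * 1e6).

    Samples with zero library size are excluded with a warning.
    """
    lib = matrix.library_sizes
    keep = lib[lib > 0].index
    for sample in matrix.counts.columns.difference(keep):
        logger.warning("sample %s has zero library size; excluded", sample)
    counts = matrix.counts[keep].astype(float)
    return np.log2((counts + pseudocount).div(lib[keep], axis=1) * 1e6)


def fragment_differential(
    norm: pd.DataFrame,
    design: Mapping[str, str],
    prior_df: float = 4.0,
    contrast: tuple[str, str] = ("dn", "control"),
) -> pd.DataFrame:
    """Moderated two-sample t test per fragment.

    log2FC = mean(perturbation) - mean(control) of the normalised values.
    The per-fragment sample variance is shrunk toward the across-fragment
    mean variance with prior weight ``prior_df`` (empirical-Bayes scalar
    shrinkage); the t statistic then has df_residual + prior_df degrees of
    freedom.  At prior_df=0 this is exactly the ordinary equal-variance
    two-sample t test.
    """
    test_label, ctrl_label = contrast
    test_cols = [s for s in norm.columns if design[s] == test_label]
    ctrl_cols = [s for s in norm.columns if design[s] == ctrl_label]
    n1, n2 = len(test_cols), len(ctrl_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            "each condition needs >=2 samples for variance estimation"
        )
    x1 = norm[test_cols].to_numpy()
    x2 = norm[ctrl_cols].to_numpy()
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    lfc = m1 - m2
    df_resid = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    s2_prior = float(s2.mean())
    if prior_df > 0:
        s2_mod = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    else:
        s2_mod = s2
    df_total = df_resid + prior_df
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (lfc != 0), np.inf * np.sign(lfc), t)
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.where((se == 0) & (lfc == 0), 1.0, p)
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "s2_mod": s2_mod,
            "mean_abund": (m1 * n1 + m2 * n2) / (n1 + n2),
        },
        index=norm.index,
    )
    return out


def simes(pvals: np.ndarray) -> float:
    """Simes combined p: min over ordered p of n * p_(i) / i."""
    p = np.sort(np.asarray(pvals, dtype=float))
    n = len(p)
    return float(np.min(n * p / np.arange(1, n + 1)))


def merge_fragments_to_peaks(
    stats: pd.DataFrame,
    fragments: pd.DataFrame,
    site_p_threshold: float = 1e-5,
    tol: int = 195,
    max_width: int = 5000,
    combine: str = "simes",
) -> pd.DataFrame:
    """Chain significant fragments into peaks and combine their p-values.

    Fragments with p < ``site_p_threshold`` enter clustering.  Consecutive
    qualifying fragments on a contig are chained while the gap between them
    is <= ``tol`` bp; a chain is split before a fragment that would push its
    span beyond ``max_width``.  Combined peak p is the Simes statistic over
    member p-values (``combine="bonferroni"`` gives min-p Bonferroni);
    direction is the sign of the mean member log2FC.
    """
    if combine not in ("simes", "bonferroni"):
        raise ValueError(f"unknown combine rule {combine!r}")
    qual = stats[stats["p"] < site_p_threshold]
    if qual.empty:
        return pd.DataFrame(
            columns=[
                "contig", "start", "end", "n_fragments", "members",
                "p", "log2fc", "direction",
            ]
        )
    merged = qual.join(fragments)
    peaks = []
    for contig, grp in merged.groupby("contig", sort=False):
        grp = grp.sort_values("start")
        chain: list = []

        def flush(chain_rows: list) -> None:
            pv = np.array([r["p"] for r in chain_rows], dtype=float)
            if combine == "simes":
                comb = simes(pv)
            else:
                comb = float(min(1.0, len(pv) * pv.min()))
            lfcs = np.array([r["log2fc"] for r in chain_rows], dtype=float)
            mean_lfc = float(lfcs.mean())
            peaks.append(
                {
                    "contig": contig,
                    "start": int(min(r["start"] for r in chain_rows)),
                    "end": int(max(r["end"] for r in chain_rows)),
                    "n_fragments": len(chain_rows),
                    "members": [r["__id"] for r in chain_rows],
                    "p": comb,
                    "log2fc": mean_lfc,
                    "direction": "up" if mean_lfc > 0 else "down",
                }
            )

        for fid, row in grp.iterrows():
            rec = row.to_dict()
            rec["__id"] = fid
            if not chain:
                chain = [rec]
                continue
            gap = rec["start"] - chain[-1]["end"]
            span = rec["end"] - chain[0]["start"]
            if gap <= tol and span <= max_width:
                chain.append(rec)
            else:
                flush(chain)
                chain = [rec]
        if chain:
            flush(chain)
    out = pd.DataFrame(peaks)
    out.index.name = "peak_id"
    return out


def peak_fdr_filter(
    peaks: pd.DataFrame,
    fdr: float = 0.05,
    min_abs_log2fc: float = 2.0,
    direction: str = "down",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BH-adjust peak p-values and apply the FDR / effect-size / sign gates.

    Returns (all peaks with a q column, the retained subset).
    """
    peaks = peaks.copy()
    if peaks.empty:
        peaks["q"] = pd.Series(dtype=float)
        return peaks, peaks
    peaks["q"] = multipletests(peaks["p"].to_numpy(), method="fdr_bh")[1]
    keep = (peaks["q"] <= fdr) & (peaks["log2fc"].abs() >= min_abs_log2fc)
    if direction == "down":
        keep &= peaks["log2fc"] < 0
    elif direction == "up":
        keep &= peaks["log2fc"] > 0
    elif direction != "any":
        raise ValueError(f"unknown direction {direction!r}")
    return peaks, peaks[keep]


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    genes: Sequence[GeneModel],
    promoter_upstream: int = 0,
) -> pd.DataFrame:
    """Assign peaks to every gene they overlap by >=1 bp.

    The gene span may be extended ``promoter_upstream`` bp upstream of the
    TSS.  Per gene the evidence is the minimum peak q and the log2FC of that
    best (smallest-q) overlapping peak.  Peaks overlapping no gene are kept
    in a row with gene_id "." so nothing silently disappears.
    """
    rows = []
    assigned: set = set()
    for gene in genes:
        gstart, gend = gene.start, gene.end
        if promoter_upstream:
            if gene.strand == "+":
                gstart = max(0, gstart - promoter_upstream)
            else:
                gend = gend + promoter_upstream
        sub = peaks[
            (peaks["contig"] == gene.contig)
            & (peaks["start"] < gend)
            & (peaks["end"] > gstart)
        ]
        if sub.empty:
            continue
        has_q = "q" in sub.columns
        best = sub.loc[sub["q"].idxmin()] if has_q else sub.loc[sub["p"].idxmin()]
        assigned.update(sub.index)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "n_peaks": len(sub),
                "best_peak": best.name,
                "q": float(best["q"]) if has_q else np.nan,
                "p": float(best["p"]),
                "log2fc": float(best["log2fc"]),
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene_id", "n_peaks", "best_peak", "q", "p", "log2fc"]
    )
    unassigned = [i for i in peaks.index if i not in assigned]
    out.attrs["unassigned_peaks"] = unassigned
    return out


def _interval_contains(intervals: list[tuple[int, int]], pos: float) -> bool:
    return any(s <= pos < e for s, e in intervals)


def annotate_peak_features(
    peaks: pd.DataFrame,
    genes: Sequence[GeneModel],
    downstream: int = 3000,
) -> pd.DataFrame:
    """Classify each peak midpoint onto genomic features.

    Categories, highest priority first: Promoter <=1kb / 1-2kb / 2-3kb
    (upstream of the TSS on the gene's strand), 5' UTR, 3' UTR, Exon,
    Intron, Downstream <=3kb past the 3' end, Distal Intergenic.  A midpoint
    touching several genes takes the highest-priority label available.
    Returns the category table with counts and percentages.
    """
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    labels = []
    for _, peak in peaks.iterrows():
        mid = (peak["start"] + peak["end"]) / 2.0
        candidates: list[str] = []
        for gene in by_contig.get(peak["contig"], []):
            if gene.strand == "+":
                d_up = gene.tss - mid
                tail = mid - gene.end  # past 3' end
            else:
                d_up = mid - gene.tss
                tail = gene.start - mid
            if 0 < d_up <= 1000:
                candidates.append("Promoter (<=1kb)")
            elif 1000 < d_up <= 2000:
                candidates.append("Promoter (1-2kb)")
            elif 2000 < d_up <= 3000:
                candidates.append("Promoter (2-3kb)")
            if gene.start <= mid < gene.end:
                if _interval_contains(gene.utr5, mid):
                    candidates.append("5' UTR")
                elif _interval_contains(gene.utr3, mid):
                    candidates.append("3' UTR")
                elif _interval_contains(gene.exons, mid):
                    candidates.append("Exon")
                else:
                    candidates.append("Intron")
            if 0 < tail <= downstream:
                candidates.append("Downstream (<=3kb)")
        if not candidates:
            label = "Distal Intergenic"
        else:
            label = min(candidates, key=FEATURE_PRIORITY.index)
        labels.append(label)
    counts = pd.Series(labels).value_counts()
    table = pd.DataFrame(
        {
            "count": [int(counts.get(c, 0)) for c in FEATURE_PRIORITY],
        },
        index=pd.Index(FEATURE_PRIORITY, name="category"),
    )
    total = table["count"].sum()
    table["percent"] = 100.0 * table["count"] / total if total else 0.0
    table.attrs["peak_labels"] = labels
    return table


def tss_metaprofile(
    signal: pd.Series,
    fragments: pd.DataFrame,
    genes: Sequence[GeneModel],
    window_bp: int = 2000,
    bin_bp: int = 50,
) -> pd.DataFrame:
    """Mean fragment signal by distance to TSS, strand-oriented.

    For each gene, fragments whose midpoint falls within +/- window of the
    TSS are binned by signed distance (downstream positive; minus-strand
    genes flipped); the profile is the per-bin mean over genes of the
    per-gene mean signal.
    """
    edges = np.arange(-window_bp, window_bp + bin_bp, bin_bp)
    centers = (edges[:-1] + edges[1:]) / 2.0
    acc = np.zeros(len(centers))
    cnt = np.zeros(len(centers))
    frag = fragments.join(signal.rename("signal"))
    mids = (frag["start"].to_numpy() + frag["end"].to_numpy()) / 2.0
    for gene in genes:
        on_contig = frag["contig"].to_numpy() == gene.contig
        d = mids - gene.tss
        if gene.strand == "-":
            d = -d
        sel = on_contig & (d >= -window_bp) & (d < window_bp)
        if not sel.any():
            continue
        idx = np.digitize(d[sel], edges) - 1
        vals = frag["signal"].to_numpy()[sel]
        binned = np.full(len(centers), np.nan)
        for b in np.unique(idx):
            binned[b] = vals[idx == b].mean()
        seen = ~np.isnan(binned)
        acc[seen] += binned[seen]
        cnt[seen] += 1
    profile = np.where(cnt > 0, acc / np.where(cnt > 0, cnt, 1), np.nan)
    return pd.DataFrame({"distance": centers, "signal": profile})


def differential_occupancy_genes(
    matrix: FragmentCountMatrix,
    genes: Sequence[GeneModel],
    pseudocount: float = 0.5,
    prior_df: float = 4.0,
    site_p_threshold: float = 1e-5,
    tol: int = 195,
    max_width: int = 5000,
    fdr: float = 0.05,
    min_abs_log2fc: float = 2.0,
    direction: str = "down",
    contrast: tuple[str, str] = ("dn", "control"),
) -> dict:
    """Full fragment-to-gene differential occupancy pipeline.

    Fragments with zero counts in every sample are removed before testing.
    Returns a dict with the intermediate tables and the filtered gene table.
    """
    nonzero = matrix.counts.sum(axis=1) > 0
    sub = FragmentCountMatrix(
        matrix.fragments[nonzero],
        matrix.counts[nonzero],
        matrix.conditions,
        matrix.dropped,
    )
    norm = normalize_log2(sub, pseudocount=pseudocount)
    stats = fragment_differential(
        norm, sub.conditions, prior_df=prior_df, contrast=contrast
    )
    peaks = merge_fragments_to_peaks(
        stats, sub.fragments,
        site_p_threshold=site_p_threshold, tol=tol, max_width=max_width,
    )
    peaks_q, retained = peak_fdr_filter(
        peaks, fdr=fdr, min_abs_log2fc=min_abs_log2fc, direction=direction
    )
    gene_table = assign_peaks_to_genes(retained, genes)
    return {
        "norm": norm,
        "stats": stats,
        "peaks": peaks_q,
        "retained_peaks": retained,
        "gene_table": gene_table,
        "genes": sorted(gene_table["gene_id"].tolist()),
    }


def peaks_to_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    """Write peaks as BED6+ (name = peak id, score = -10*log10 q, then
    log2fc, p, q, n_fragments columns)."""
    with open(path, "w") as fh:
        for pid, row in peaks.iterrows():
            q = row.get("q", np.nan)
            score = int(min(1000, -10 * math.log10(q))) if q and q > 0 else 1000
            fh.write(
                f"{row['contig']}\t{row['start']}\t{row['end']}\tpeak{pid}\t"
                f"{score}\t.\t{row['log2fc']:.4f}\t{row['p']:.3g}\t"
                f"{q:.3g}\t{row['n_fragments']}\n"
            )


def signal_to_bedgraph(signal: pd.Series, fragments: pd.DataFrame,
                       path: str | Path) -> None:
    """Write a per-fragment signal track as bedGraph."""
    frame = fragments.join(signal.rename("value")).dropna(subset=["value"])
    with open(path, "w") as fh:
        for _, row in frame.iterrows():
            fh.write(
                f"{row['contig']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"{row['value']:.5f}\n"
            )
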