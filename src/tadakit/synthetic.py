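"""Synthetic data generators with planted ground truth.

Every generator is a pure function of its seed and parameters and returns,
besides the data in the same containers/formats the analysis modules
consume, a :class:`TruthRecord` sufficient to compute the expected outcome
of the corresponding recovery test without re-simulation.  Count data are
negative binomial throughout (overdispersion is the regime the moderated
statistics must handle); GATC motifs are placed with geometric inter-site
spacing, the simplest stationary model of motif occurrence, whose median
fragment length is pinned by the closed form median ≈ 4 + (m - 4)·ln 2 for
start-to-start spacing mean m.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gatc import GenomeSequence, find_gatc_sites, build_fragments, GatcFragmentMap
from .damid import GeneModel, fragments_frame
from .phenotype import ActivitySeries, make_light_schedule, MIN_PER_DAY
from .propeptide import Prepropeptide

logger = logging.getLogger("tadakit")

BASES = np.array(list("ACGT"))


@dataclass
class TruthRecord:
    """Planted parameters of one generator call (JSON-serialisable)."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(s)
        return s


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float
               ) -> np.ndarray:
    """Negative binomial draws with mean mu and size (inverse-dispersion
    shape) ``dispersion``; variance mu + mu^2/dispersion."""
    mu = np.asarray(mu, dtype=float)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, np.clip(p, 1e-12, 1.0))


# ---------------------------------------------------------------------------
# genome + gene models


def gen_genome(
    n_contigs: int = 1,
    length: int = 1_000_000,
    gatc_spacing_mean: float = 350.0,
    seed: int = 0,
    gene_length: int = 8000,
    gene_gap: int = 2000,
) -> tuple[GenomeSequence, list[GeneModel], TruthRecord]:
    """GATC-punctuated random genome with tiled gene models.

    Motif starts are placed with spacing 4 + Geometric(mean
    ``gatc_spacing_mean`` - 4); accidental GATCs arising in the random
    background are mutated away so the spacing law (and hence the expected
    median fragment length) holds exactly.  Genes of ``gene_length`` bp are
    tiled with ``gene_gap`` bp spacers on alternating strands, each with two
    exons and terminal UTRs.
    """
    if n_contigs <= 0:
        raise ValueError("n_contigs must be positive")
    if gatc_spacing_mean <= 4:
        raise ValueError("gatc_spacing_mean must exceed the motif length")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    planted_sites: dict[str, list[int]] = {}
    for ci in range(n_contigs):
        name = f"contig{ci + 1}"
        seq = rng.choice(BASES, size=length)
        # plant motifs
        sites = []
        pos = int(rng.integers(0, int(gatc_spacing_mean)))
        p_geom = 1.0 / (gatc_spacing_mean - 4.0)
        while pos + 4 <= length:
            sites.append(pos)
            pos += 4 + int(rng.geometric(p_geom))
        arr = seq.copy()
        for s in sites:
            arr[s : s + 4] = list("GATC")
        # remove accidental motifs created by the random background
        planted = set(sites)
        text = "".join(arr)
        while True:
            stray = [
                i
                for i in _find_all(text, "GATC")
                if i not in planted
            ]
            if not stray:
                break
            lst = list(text)
            for i in stray:
                lst[i] = "C"
            text = "".join(lst)
        contigs[name] = text
        planted_sites[name] = sites
        # tile genes
        pos = 500
        gi = 0
        while pos + gene_length + gene_gap < length:
            strand = "+" if gi % 2 == 0 else "-"
            s, e = pos, pos + gene_length
            exon1 = (s, s + gene_length // 4)
            exon2 = (s + gene_length // 2, e)
            if strand == "+":
                utr5 = [(s, s + 150)]
                utr3 = [(e - 150, e)]
            else:
                utr5 = [(e - 150, e)]
                utr3 = [(s, s + 150)]
            genes.append(
                GeneModel(
                    f"{name}_g{gi + 1}", name, strand, s, e,
                    exons=[exon1, exon2], utr5=utr5, utr3=utr3,
                )
            )
            pos = e + gene_gap
            gi += 1
    truth = TruthRecord(
        "gen_genome",
        seed,
        {
            "n_contigs": n_contigs,
            "length": length,
            "gatc_spacing_mean": gatc_spacing_mean,
            "expected_median_fragment": 4 + (gatc_spacing_mean - 4) * float(np.log(2)),
            "n_genes": len(genes),
        },
    )
    return GenomeSequence(contigs), genes, truth


def _find_all(text: str, motif: str) -> list[int]:
    out = []
    i = text.find(motif)
    while i != -1:
        out.append(i)
        i = text.find(motif, i + 1)
    return out


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.contig}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )
            for s, e in g.utr5:
                fh.write(
                    f"{g.contig}\t.\tfive_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )
            for s, e in g.utr3:
                fh.write(
                    f"{g.contig}\t.\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# DamID reads


def gen_tada_reads(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    target_genes: Sequence[str],
    base_rate: float = 350.0,
    effect_fold: float = 4.0,
    n_control: int = 3,
    n_dn: int = 2,
    dispersion: float = 150.0,
    intergenic_rate_frac: float = 0.3,
    read_length: int = 75,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict[str, str], GatcFragmentMap, TruthRecord]:
    """Aligned-read intervals emulating a Pol II DamID contrast.

    Reads per fragment are negative binomial; fragments inside a gene span
    draw mean ``base_rate`` scaled by the fragment length (longer bins catch
    more reads), intergenic fragments a fraction of it.  In the
    perturbation ("dn") samples the means of fragments in target genes are
    divided by ``effect_fold``.  The replicate design defaults to 3 control
    + 2 perturbation samples.  Returns per-sample read frames, the sample
    condition labels, the fragment map, and the truth record.
    """
    if effect_fold < 1:
        raise ValueError("effect_fold must be >= 1")
    rng = np.random.default_rng(seed)
    frag_map = build_fragments(find_gatc_sites(genome))
    frags = fragments_frame(frag_map)
    mids = (frags["start"] + frags["end"]) / 2.0
    # fragment -> containing gene (midpoint rule)
    frag_gene = np.full(len(frags), "", dtype=object)
    for g in genes:
        sel = (
            (frags["contig"] == g.contig)
            & (mids >= g.start)
            & (mids < g.end)
        ).to_numpy()
        frag_gene[sel] = g.gene_id
    lengths = (frags["end"] - frags["start"]).to_numpy()
    rel_len = lengths / lengths.mean()
    base_mu = np.where(frag_gene != "", base_rate, base_rate * intergenic_rate_frac)
    base_mu = base_mu * rel_len
    in_target = np.isin(frag_gene, list(target_genes))
    samples: dict[str, pd.DataFrame] = {}
    conditions: dict[str, str] = {}
    contig_len = {name: len(s) for name, s in genome.contigs.items()}
    for i in range(n_control + n_dn):
        is_dn = i >= n_control
        name = f"dn_{i - n_control + 1}" if is_dn else f"ctrl_{i + 1}"
        conditions[name] = "dn" if is_dn else "control"
        mu = base_mu.copy()
        if is_dn:
            mu[in_target] = mu[in_target] / effect_fold
        counts = _nb_counts(rng, mu, dispersion)
        contigs_arr = frags["contig"].to_numpy()
        starts = frags["start"].to_numpy()
        ends = frags["end"].to_numpy()
        rep = np.repeat(np.arange(len(frags)), counts)
        span = ends[rep] - starts[rep]
        mid_pos = starts[rep] + (rng.random(len(rep)) * span).astype(int)
        frag_max = np.array([contig_len[c] for c in contigs_arr]) - read_length
        read_start = np.clip(mid_pos - read_length // 2, 0, frag_max[rep])
        samples[name] = pd.DataFrame(
            {
                "contig": contigs_arr[rep],
                "start": read_start,
                "end": read_start + read_length,
            }
        )
    truth = TruthRecord(
        "gen_tada_reads",
        seed,
        {
            "target_genes": sorted(target_genes),
            "effect_fold": effect_fold,
            "base_rate": base_rate,
            "n_control": n_control,
            "n_dn": n_dn,
            "dispersion": dispersion,
        },
    )
    return samples, conditions, frag_map, truth


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    reads.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# single-cell matrix


def gen_sc_matrix(
    n_cells: int = 1000,
    n_genes: int = 2000,
    n_clusters: int = 5,
    signature: Sequence[str] | None = None,
    n_signature: int = 100,
    enriched_cluster: int = 0,
    enriched_frac: float = 0.1,
    lift: float = 5.0,
    alk_gene: str = "Alk",
    coexpressed_genes: Sequence[str] = (),
    dispersion: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, TruthRecord]:
    """Gene x cell negative-binomial counts with one signature-lifted cluster.

    Cluster ``enriched_cluster`` holds ``enriched_frac`` of the cells and
    multiplies the signature genes' means by ``lift``.  A designated
    receptor gene (``alk_gene``) and any ``coexpressed_genes`` are elevated
    in the same cells, giving the co-expression structure the integration
    filter expects.  Gene ids are g0001.. unless an explicit signature list
    is supplied.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    if signature is None:
        signature = gene_ids[:n_signature]
    else:
        signature = list(signature)
        missing = set(signature) - set(gene_ids)
        if missing:
            gene_ids = gene_ids[: n_genes - len(missing)] + sorted(missing)
    extra = [g for g in [alk_gene, *coexpressed_genes] if g not in gene_ids]
    if extra:
        gene_ids = gene_ids[: n_genes - len(extra)] + extra
    n_enriched = max(1, int(round(enriched_frac * n_cells)))
    labels = np.zeros(n_cells, dtype=int)
    if n_clusters > 1:
        labels[n_enriched:] = 1 + rng.integers(0, n_clusters - 1,
                                               size=n_cells - n_enriched)
        labels[:n_enriched] = enriched_cluster
        # relabel so enriched_cluster id is respected even if not 0
        if enriched_cluster != 0:
            labels[labels == enriched_cluster] = -1
            labels[:n_enriched] = enriched_cluster
            labels[labels == -1] = 0
    gene_mu = rng.gamma(shape=2.0, scale=1.0, size=len(gene_ids)) + 0.1
    mu = np.tile(gene_mu[:, None], (1, n_cells))
    in_sig = np.isin(gene_ids, list(signature))
    enriched_cells = labels == enriched_cluster
    mu[np.ix_(in_sig, enriched_cells)] *= lift
    alk_idx = gene_ids.index(alk_gene)
    mu[alk_idx, :] = 0.05
    mu[alk_idx, enriched_cells] = 5.0
    for g in coexpressed_genes:
        gi = gene_ids.index(g)
        mu[gi, :] = 0.05
        mu[gi, enriched_cells] = 5.0
    counts = _nb_counts(rng, mu, dispersion)
    cells = [f"cell{i + 1:05d}" for i in range(n_cells)]
    matrix = pd.DataFrame(counts, index=gene_ids, columns=cells)
    label_s = pd.Series(labels, index=cells, name="cluster")
    truth = TruthRecord(
        "gen_sc_matrix",
        seed,
        {
            "signature": sorted(signature),
            "enriched_cluster": int(enriched_cluster),
            "enriched_frac": enriched_frac,
            "lift": lift,
            "alk_gene": alk_gene,
            "coexpressed_genes": list(coexpressed_genes),
        },
    )
    return matrix, label_s, truth


# ---------------------------------------------------------------------------
# bulk DE tables


def gen_bulk_de(
    n_genes: int = 200,
    planted: Mapping[str, tuple[float, float]] | None = None,
    noise_sd: float = 0.2,
    gene_ids: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Two differential-expression tables (gain- and loss-of-function).

    Observed log2FC = planted effect + Gaussian noise; the p-value comes
    from the z statistic observed/se with se = noise_sd (se = 1 when
    noise_sd = 0, so the noiseless case still yields a deterministic p).
    Genes without a planted effect have effect 0 in both contrasts.
    """
    rng = np.random.default_rng(seed)
    planted = dict(planted or {})
    if gene_ids is None:
        gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    gene_ids = list(gene_ids)
    for g in planted:
        if g not in gene_ids:
            gene_ids.append(g)
    se = noise_sd if noise_sd > 0 else 1.0
    tables = []
    for which in (0, 1):  # 0 = GOF, 1 = LOF
        effects = np.array([planted.get(g, (0.0, 0.0))[which] for g in gene_ids])
        obs = effects + rng.normal(0.0, noise_sd, size=len(gene_ids))
        z = obs / se
        p = 2.0 * norm.sf(np.abs(z))
        tables.append(
            pd.DataFrame({"gene_id": gene_ids, "log2fc": obs, "p": p})
        )
    truth = TruthRecord(
        "gen_bulk_de", seed,
        {"planted": {g: list(v) for g, v in planted.items()},
         "noise_sd": noise_sd, "n_genes": len(gene_ids)},
    )
    return tables[0], tables[1], truth


# ---------------------------------------------------------------------------
# DAM activity series


def gen_dam_series(
    n_flies: int = 8,
    days: int = 7,
    period_min: float = 1440.0,
    amplitude: float = 0.8,
    mean_rate: float = 20.0,
    bin_minutes: int = 5,
    bimodal: bool = True,
    peak_sharpness: float = 6.0,
    sleep_block_hours: float = 0.0,
    death_day: Mapping[int, int] | None = None,
    ld_days: int | None = None,
    photoperiod_hours: float = 12.0,
    seed: int = 0,
) -> tuple[list[ActivitySeries], TruthRecord]:
    """Poisson beam-crossing series with a known circadian period.

    rate(t) = mean_rate * (1 + amplitude * w(t/period)).  The default
    waveform is crepuscular — sharp morning and evening activity peaks
    (von-Mises-type bumps of concentration ``peak_sharpness``, evening peak
    at 80% of the morning one), standardised to zero mean and unit maximum —
    which is what fly locomotor records look like; ``bimodal=False`` gives a
    pure cosine instead.  ``sleep_block_hours`` forces a zero block in
    the middle of every night (a guaranteed sleep bout); ``death_day`` maps
    fly index -> day from which all counts are zero.  ``ld_days`` sets the
    LD->DD switch day for the attached light schedule.  Recordings start at
    lights-on (ZT0).
    """
    if not 1000 <= period_min <= 2000:
        raise ValueError("period must be within 1000-2000 minutes")
    if amplitude < 0 or amplitude > 1:
        raise ValueError("amplitude must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_bins = days * MIN_PER_DAY // bin_minutes
    t_min = np.arange(n_bins) * bin_minutes
    phase = 2.0 * np.pi * t_min / period_min
    if bimodal:
        raw = np.exp(peak_sharpness * (np.cos(phase) - 1.0)) + 0.8 * np.exp(
            peak_sharpness * (np.cos(phase - np.pi) - 1.0)
        )
        w = raw - raw.mean()
        w = w / np.abs(w).max()
    else:
        w = np.cos(phase)
    rate = mean_rate * (1.0 + amplitude * w)
    light = make_light_schedule(n_bins, bin_minutes, photoperiod_hours,
                                dd_from_day=ld_days)
    death_day = dict(death_day or {})
    series = []
    for fi in range(n_flies):
        counts = rng.poisson(rate)
        if sleep_block_hours > 0:
            block = int(sleep_block_hours * 60 / bin_minutes)
            for d in range(days):
                night_mid = (d * MIN_PER_DAY + int(photoperiod_hours * 60)
                             + (MIN_PER_DAY - int(photoperiod_hours * 60)) // 2
                             ) // bin_minutes
                counts[night_mid - block // 2 : night_mid - block // 2 + block] = 0
        if fi in death_day:
            counts[death_day[fi] * MIN_PER_DAY // bin_minutes :] = 0
        series.append(
            ActivitySeries(
                f"fly{fi + 1}", bin_minutes, counts, light,
                datetime(2024, 1, 1, 8, 0, 0),
            )
        )
    truth = TruthRecord(
        "gen_dam_series", seed,
        {
            "period_min": period_min, "amplitude": amplitude,
            "mean_rate": mean_rate, "days": days, "bin_minutes": bin_minutes,
            "death_day": {str(k): v for k, v in death_day.items()},
            "ld_days": ld_days,
        },
    )
    return series, truth


def write_dam_file(series_list: Sequence[ActivitySeries], path: str | Path) -> None:
    """Write series as a Trikinetics DAM monitor text file (32 channels,
    unused channels zero-filled)."""
    if not series_list:
        raise ValueError("no series to write")
    if len(series_list) > 32:
        raise ValueError("a DAM monitor has 32 channels")
    n = len(series_list[0].counts)
    bw = series_list[0].bin_minutes
    start = series_list[0].start or datetime(2024, 1, 1, 8, 0, 0)
    mat = np.zeros((n, 32), dtype=int)
    for i, s in enumerate(series_list):
        if len(s.counts) != n or s.bin_minutes != bw:
            raise ValueError("series must share length and bin width")
        mat[:, i] = s.counts
    with open(path, "w") as fh:
        for ri in range(n):
            stamp = start + pd.Timedelta(minutes=bw * ri)
            date = stamp.strftime("%d %b %y")
            time = stamp.strftime("%H:%M:%S")
            device = ["1", "0", "0", "0", "0", "0"]
            fields = [str(ri + 1), date, time, "1", *device,
                      *[str(int(x)) for x in mat[ri]]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# prepropeptides

DIBASIC_MOTIFS = ["KR", "KK", "RR", "RK"]
# residues for random segments: no C (the emulated precursor class lacks
# cysteines) and no K/R (so planted motifs are the only cleavage sites)
SEGMENT_ALPHABET = np.array(list("ADEFGHILMNPQSTVWY"))


def gen_prepropeptide(
    n_segments: int = 4,
    segment_length: int = 20,
    q_runs: Sequence[int] = (),
    amidated_segments: Sequence[int] = (),
    signal_peptide_len: int = 20,
    seed: int = 0,
) -> tuple[Prepropeptide, TruthRecord]:
    """Random prepropeptide with planted dibasic sites, Q-runs and amidation.

    ``n_segments`` peptide segments are joined by dibasic motifs drawn from
    KR/KK/RR/RK; segment indices in ``amidated_segments`` end in G (an
    amidation signal); ``q_runs`` lengths are planted one per segment from
    the first onward.  The truth record carries the exact cleavage map on
    the proprotein.
    """
    if n_segments < 1:
        raise ValueError("need at least one segment")
    rng = np.random.default_rng(seed)
    signal = "M" + "".join(rng.choice(list("LVAFIST"), size=signal_peptide_len - 1))
    segments = []
    for si in range(n_segments):
        seg = list(rng.choice(SEGMENT_ALPHABET, size=segment_length))
        # avoid accidental Q-runs >= 3 so the planted ones are the only ones
        for i in range(2, len(seg)):
            if seg[i] == "Q" and seg[i - 1] == "Q" and seg[i - 2] == "Q":
                seg[i] = "A"
        if si < len(q_runs):
            run = "Q" * q_runs[si]
            insert_at = 2
            seg = seg[:insert_at] + list(run) + seg[insert_at:]
            # guard the run's flanks
            if seg[insert_at - 1] == "Q":
                seg[insert_at - 1] = "A"
            after = insert_at + len(run)
            if after < len(seg) and seg[after] == "Q":
                seg[after] = "A"
        if si in amidated_segments:
            seg.append("G")
        elif seg[-1] == "G":
            seg[-1] = "A"
        segments.append("".join(seg))
    motifs = [DIBASIC_MOTIFS[int(rng.integers(0, 4))] for _ in range(n_segments - 1)]
    prop = segments[0]
    cleavage_positions = []
    for seg, motif in zip(segments[1:], motifs):
        prop += motif
        cleavage_positions.append(len(prop))  # 1-based last residue of motif
        prop += seg
    seq = signal + prop
    prepro = Prepropeptide("synthetic_prepro", seq, signal_peptide_len)
    truth = TruthRecord(
        "gen_prepropeptide", seed,
        {
            "segments": segments,
            "motifs": motifs,
            "cleavage_positions": cleavage_positions,
            "amidated_segments": list(amidated_segments),
            "q_runs": list(q_runs),
            "signal_peptide_len": signal_peptide_len,
        },
    )
    return prepro, truth


# ---------------------------------------------------------------------------
# synthetic neuropeptide-precursor stand-in

# NOT a natural protein.  A 445-aa sequence constructed to carry the
# published composition facts of the CG4577/Spar-PA precursor so the
# composition and processing machinery can be exercised without a database
# fetch: 27-aa signal peptide, 43 glutamines with six tandem repeats at
# positions 48-56, 59-62, 64-71, 116-118, 120-122 and 148-150, no cysteine,
# integer net charge (K+R)-(D+E) = -6, pI 5.10 (Bjellqvist set), and the
# mass-spec-confirmed processing cassette KR|SEEASAVPTADKK|FNDMRLKR|
# DTQLNPADMLALVALVEAGERA|KR embedded between dibasic cleavage sites.
SYNTHETIC_SPAR_LIKE_SEQUENCE = (
    "MLAVLFSTLVVLAASSLAVFATLSIAAAEATKGTSVEGTSLALNVVAQQQQQQQQQKTQQQQLQQQQ"
    "QQQQNEGKSLTPVAVEPTKDNSNSVPGPPNSGGVNPPGVNNLETGVANQQQTQQQSVGANSDPVSAV"
    "KLPVSAPNPSGRGQQQKAGNLDPTVAVGSTKLDAGRLTEKSAPRVELVAGPNSSLVLRTSETEPGDQ"
    "NLSEKTRARLPAVPRGGTEATPQPALDPTNPDNSYYQNNVLPPPKQGTEAYPTDTHRPARGAAPSNL"
    "QGVDSLKRSEEASAVPTADKKFNDMRLKRDTQLNPADMLALVALVEAGERAKRANSQSVNDVVKPSN"
    "SAVAEVLVGSNGKPNSQGQSQLQLNTDALVGPVESVTSARGANSGVLSSLSDSTTNGDPTTVTPNGD"
    "LTTANLVNTDLAGTTTPEVQTATPRPDAGNQLVTTTSSLSGVP"
)


def synthetic_spar_like(signal_peptide_len: int = 27) -> Prepropeptide:
    """Synthetic stand-in for a glutamine-rich neuropeptide precursor.

    See :data:`SYNTHETIC_SPAR_LIKE_SEQUENCE`; this is a constructed
    sequence, not the FlyBase record, and is labelled synthetic for that
    reason.  The signal-peptide boundary defaults to 27 (the value reported
    for the modelled precursor; its figure legend marks residues 1-26, a
    one-residue discrepancy documented in the methods note).
    """
    return Prepropeptide(
        "synthetic-spar-like", SYNTHETIC_SPAR_LIKE_SEQUENCE, signal_peptide_len
    )
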