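"""Canonical neuropeptide-precursor processing and peptide mass matching.

The model is the textbook secretory-pathway chain: the signal peptide is
removed (its boundary is an input — signal-peptide prediction is not
reimplemented), prohormone convertases cleave C-terminally of poly-/dibasic
motifs (KR, KK, RR, RK and longer K/R runs), carboxypeptidase activity trims
the exposed C-terminal basic residues, and a remaining C-terminal glycine is
converted into a C-terminal amide.  Monoisotopic masses of the raw
(convertase product) and mature forms are matched against observed
peptidomics masses within a ppm tolerance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

logger = logging.getLogger("tadakit")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
WATER_MONO = 18.010565
AMIDATION_DELTA = -0.984016  # C-terminal OH -> NH2

# Bjellqvist pKa set; fixed so pI values are bit-stable.
PKA_POSITIVE = {"Nterm": 7.50, "K": 10.00, "R": 12.00, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00}


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    for i, aa in enumerate(seq, start=1):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"non-amino-acid character {aa!r} at position {i}")
    return seq


@dataclass
class Prepropeptide:
    """A precursor protein with an externally supplied signal-peptide length."""

    id: str
    sequence: str
    signal_peptide_len: int = 27
    isoform: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        self.sequence = _validate_sequence(self.sequence)
        if not 0 <= self.signal_peptide_len < len(self.sequence):
            raise ValueError("signal peptide length must be < sequence length")

    @property
    def propeptide(self) -> str:
        return self.sequence[self.signal_peptide_len:]

    @classmethod
    def from_fasta(cls, path: str | Path, signal_peptide_len: int = 27):
        from Bio import SeqIO

        out = []
        for rec in SeqIO.parse(str(path), "fasta"):
            out.append(cls(rec.id, str(rec.seq), signal_peptide_len))
        return out


@dataclass
class CleavageSite:
    position: int  # 1-based index of the LAST residue of the basic run
    motif: str


def find_cleavage_sites(sequence: str) -> list[CleavageSite]:
    """Maximal K/R runs of length >= 2, each reported once.

    The site position is the run's last residue (1-based), so "AKKRA" yields
    a single KKR site at position 4.  Singleton K/R residues are not
    convertase sites in this model (monobasic cleavage excluded).
    """
    sequence = _validate_sequence(sequence)
    sites = []
    for m in re.finditer(r"[KR]{2,}", sequence):
        sites.append(CleavageSite(position=m.end(), motif=m.group()))
    return sites


@dataclass
class PredictedPeptide:
    start: int  # 1-based inclusive, on the proprotein (signal peptide removed)
    end: int
    raw: str  # convertase product, still C-terminally basic
    mature: str  # after carboxypeptidase trimming and amidation
    trimmed: bool
    amidated: bool

    @property
    def raw_mass(self) -> float:
        return monoisotopic_mass(self.raw)

    @property
    def mature_mass(self) -> float:
        return monoisotopic_mass(self.mature, amidated=self.amidated)


def trim_basic(peptide: str) -> str:
    """Carboxypeptidase step: iteratively remove C-terminal K/R."""
    return peptide.rstrip("KR")


def mature_form(raw: str) -> tuple[str, bool, bool]:
    """Trim C-terminal basics, then amidate if the new C-terminus is G.

    Returns (mature sequence, trimmed flag, amidated flag).  Trimming is
    idempotent and amidation fires only on a trimmed C-terminal glycine.
    """
    trimmed = trim_basic(raw)
    was_trimmed = trimmed != raw
    if trimmed.endswith("G"):
        return trimmed[:-1], was_trimmed, True
    return trimmed, was_trimmed, False


def enumerate_peptides(
    prepro: Prepropeptide, sites: Sequence[CleavageSite] | None = None
) -> list[PredictedPeptide]:
    """Cut the proprotein after every basic motif.

    The signal peptide is removed first; ``sites`` are coordinates on the
    resulting proprotein (recomputed from it when omitted).  Each raw
    peptide runs from the residue after the previous motif through the end
    of the next motif, so concatenating raw peptides reconstructs the
    proprotein exactly.  The C-terminal tail after the last motif is itself
    a peptide; with no sites the whole proprotein is one peptide.
    """
    prop = prepro.propeptide
    if sites is None:
        sites = find_cleavage_sites(prop)
    peptides = []
    start = 1
    cut_ends = [s.position for s in sites]
    if not cut_ends or cut_ends[-1] != len(prop):
        cut_ends = cut_ends + [len(prop)]
    for end in cut_ends:
        raw = prop[start - 1 : end]
        if not raw:
            continue
        mature, was_trimmed, amidated = mature_form(raw)
        peptides.append(
            PredictedPeptide(start, end, raw, mature, was_trimmed, amidated)
        )
        start = end + 1
    return peptides


def monoisotopic_mass(sequence: str, amidated: bool = False) -> float:
    """Neutral monoisotopic mass in Da (residue masses + water).

    C-terminal amidation replaces the terminal OH by NH2 (-0.984016 Da).
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    _validate_sequence(sequence)
    m = float(_pmass.fast_mass(sequence))
    if amidated:
        m += AMIDATION_DELTA
    return m


def peptide_forms(peptides: Sequence[PredictedPeptide]) -> pd.DataFrame:
    """All searchable (peptide, form, mass) rows: raw, mature free acid and,
    where the processing model amidated it, the amidated mature form."""
    rows = []
    for i, pep in enumerate(peptides):
        rows.append({"peptide": i, "form": "raw", "sequence": pep.raw,
                     "mass": monoisotopic_mass(pep.raw)})
        if pep.mature:
            rows.append({"peptide": i, "form": "mature", "sequence": pep.mature,
                         "mass": monoisotopic_mass(pep.mature)})
            if pep.amidated:
                rows.append({"peptide": i, "form": "mature_amidated",
                             "sequence": pep.mature,
                             "mass": monoisotopic_mass(pep.mature, amidated=True)})
    return pd.DataFrame(rows)


def match_masses(
    observed: Iterable[float],
    peptides: Sequence[PredictedPeptide],
    tol_ppm: float = 8.0,
) -> pd.DataFrame:
    """Match observed masses against all predicted forms within tol_ppm.

    The comparison |obs - pred| / pred * 1e6 <= tol_ppm is inclusive at the
    boundary.  All matches are returned, sorted by |ppm error|.
    """
    forms = peptide_forms(peptides)
    rows = []
    for obs in observed:
        for _, f in forms.iterrows():
            ppm = (obs - f["mass"]) / f["mass"] * 1e6
            if abs(ppm) <= tol_ppm:
                rows.append(
                    {
                        "observed": obs,
                        "peptide": int(f["peptide"]),
                        "form": f["form"],
                        "sequence": f["sequence"],
                        "predicted": f["mass"],
                        "ppm": ppm,
                    }
                )
    out = pd.DataFrame(
        rows, columns=["observed", "peptide", "form", "sequence",
                       "predicted", "ppm"]
    )
    return out.reindex(out["ppm"].abs().sort_values().index).reset_index(drop=True)


def _charge_at(seq_counts: dict, n_term: bool, c_term: bool, ph: float) -> float:
    q = 0.0
    if n_term:
        q += 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["Nterm"]))
    for aa in ("K", "R", "H"):
        q += seq_counts.get(aa, 0) / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
    if c_term:
        q -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["Cterm"] - ph))
    for aa in ("D", "E", "C", "Y"):
        q -= seq_counts.get(aa, 0) / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return q


def isoelectric_point(sequence: str, tol: float = 1e-6) -> float:
    """pI by bisection of the Henderson-Hasselbalch net charge (Bjellqvist
    pKa set, free termini).  The charge is strictly decreasing in pH, so the
    root is unique."""
    sequence = _validate_sequence(sequence)
    counts = {aa: sequence.count(aa) for aa in AMINO_ACIDS}
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _charge_at(counts, True, True, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass
class CompositionReport:
    length: int
    counts: dict[str, int]
    q_count: int
    q_fraction: float
    q_runs: list[tuple[int, int, int]]  # (start, end, length), 1-based inclusive
    pi: float
    net_charge: int  # (#K + #R) - (#D + #E)
    charge_at_ph7: float


def composition_metrics(sequence: str, min_q_run: int = 3) -> CompositionReport:
    """Residue composition, glutamine runs, pI and net charge.

    Q-runs are maximal runs of Q of length >= ``min_q_run`` (1-based
    inclusive coordinates).  Net charge is reported both as the integer
    heuristic (#K + #R) - (#D + #E) and as the titration-model charge at
    pH 7.0.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = _validate_sequence(sequence)
    counts = {aa: sequence.count(aa) for aa in sorted(AMINO_ACIDS)}
    runs = [
        (m.start() + 1, m.end(), m.end() - m.start())
        for m in re.finditer("Q{%d,}" % min_q_run, sequence)
    ]
    return CompositionReport(
        length=len(sequence),
        counts=counts,
        q_count=counts["Q"],
        q_fraction=counts["Q"] / len(sequence),
        q_runs=runs,
        pi=isoelectric_point(sequence),
        net_charge=(counts["K"] + counts["R"]) - (counts["D"] + counts["E"]),
        charge_at_ph7=_charge_at(counts, True, True, 7.0),
    )
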