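"""GATC site and fragment map of a genome.

DamID quantifies Pol II occupancy on the intervals between consecutive DpnI
(GATC) cut sites, so the fragment map built here is the coordinate system for
every downstream step.  Coordinates are 0-based half-open throughout (BED
convention).  The DpnI cut is placed at motif start + 2 (GA^TC); any
consistent offset would do because fragments only serve as counting bins, but
the choice is fixed so outputs are bit-stable.  GATC is its own reverse
complement, so strand is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("tadakit")

MOTIF = "GATC"
CUT_OFFSET = 2  # GA^TC


@dataclass
class GenomeSequence:
    """Nucleotide sequences keyed by contig name (uppercase A/C/G/T/N)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome has no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(contigs)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class GatcSiteMap:
    """0-based start positions of every exact GATC motif, per contig."""

    sites: dict[str, np.ndarray]

    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())


@dataclass
class GatcFragmentMap:
    """Half-open DpnI fragments [start, end) per contig, sorted and contiguous."""

    fragments: dict[str, np.ndarray]  # (n, 2) int arrays

    def n_fragments(self) -> int:
        return sum(len(v) for v in self.fragments.values())

    def lengths(self) -> np.ndarray:
        parts = [frag[:, 1] - frag[:, 0] for frag in self.fragments.values() if len(frag)]
        if not parts:
            return np.empty(0, dtype=int)
        return np.concatenate(parts)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig, frags in self.fragments.items():
                for start, end in frags:
                    fh.write(f"{contig}\t{start}\t{end}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "GatcFragmentMap":
        frags: dict[str, list[list[int]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                contig, start, end = line.split("\t")[:3]
                frags.setdefault(contig, []).append([int(start), int(end)])
        return cls({c: np.array(v, dtype=int) for c, v in frags.items()})


def find_gatc_sites(genome: GenomeSequence) -> GatcSiteMap:
    """Locate every exact GATC occurrence per contig.

    N (or any ambiguity code) never matches.  Overlap is impossible for this
    motif, so a plain left-to-right ``str.find`` scan reports all sites.
    """
    sites: dict[str, np.ndarray] = {}
    for name, seq in genome.contigs.items():
        found = []
        i = seq.find(MOTIF)
        while i != -1:
            found.append(i)
            i = seq.find(MOTIF, i + 1)
        sites[name] = np.array(found, dtype=int)
    return GatcSiteMap(sites)


def build_fragments(site_map: GatcSiteMap) -> GatcFragmentMap:
    """Fragments between consecutive DpnI cuts: [site_i + 2, site_{i+1} + 2).

    Contigs with fewer than two sites yield no fragments; regions outside the
    first/last cut are excluded (a DamID fragment needs two cuts).
    """
    fragments: dict[str, np.ndarray] = {}
    for contig, sites in site_map.sites.items():
        if len(sites) < 2:
            fragments[contig] = np.empty((0, 2), dtype=int)
            continue
        cuts = sites + CUT_OFFSET
        fragments[contig] = np.column_stack([cuts[:-1], cuts[1:]])
    return GatcFragmentMap(fragments)


def median_fragment_length(
    fragment_map: GatcFragmentMap, contigs: Iterable[str] | None = None
) -> float:
    """Median fragment length in bp, pooled across the selected contigs.

    `contigs` restricts the pool (e.g. major chromosome arms only); default
    is all contigs.  Even counts average the central pair.
    """
    if contigs is not None:
        contigs = set(contigs)
        selected = GatcFragmentMap(
            {c: f for c, f in fragment_map.fragments.items() if c in contigs}
        )
    else:
        selected = fragment_map
    lengths = selected.lengths()
    if lengths.size == 0:
        raise ValueError("fragment map is empty")
    return float(np.median(lengths))


def sites_to_bed(site_map: GatcSiteMap, path: str | Path) -> None:
    """Write motif sites as BED3 with 4-bp intervals."""
    with open(path, "w") as fh:
        for contig, sites in site_map.sites.items():
            for s in sites:
                fh.write(f"{contig}\t{s}\t{s + len(MOTIF)}\n")
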