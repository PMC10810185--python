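"""Per-position nucleotide and dinucleotide composition of excised oligos.

Two views of a library's sequence composition:

* per-length nucleotide matrices (base x position, 5'-anchored), one per
  read length, mirroring the per-length composition panels;
* dinucleotide profiles of reads trimmed to a common length (20 nt),
  split into nuclear vs mitochondrial compartments.  Mitochondrial reads
  carry no excision-repair signature and serve as the specificity control:
  a flat mitochondrial pyrimidine-dinucleotide curve against a sharply
  peaked nuclear one is the assay-specificity readout.

Because reads are trimmed to 20 nt with the 3' terminus as the anchor,
positions are reported both 5'-anchored (pair start 1..k-1) and as
3'-offsets of the pair's 3' base (k-1..1); the damage peak lives at
3'-offsets 5-6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignedRead

BASES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)
PYRIMIDINE_PAIRS = ("CC", "CT", "TC", "TT")
MITO_CONTIGS = frozenset({"chrM", "MT", "M", "mtDNA"})

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_PAIR_INDEX = {p: i for i, p in enumerate(DINUCLEOTIDES)}


@dataclass
class PositionCompositionMatrix:
    """Base x position counts for reads of one length (positions from 5')."""

    read_length: int
    counts: np.ndarray  # (4, L) int
    n_reads: int
    n_excluded: int = 0  # reads containing N, excluded and logged

    @property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=0, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, self.counts / totals, 0.0)
        return freq

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies.T, columns=list(BASES))
        df.insert(0, "position", np.arange(1, self.read_length + 1))
        return df


@dataclass
class DinucleotideProfile:
    """16 x (k-1) adjacent-pair counts for k-trimmed reads of one compartment."""

    k: int
    counts: np.ndarray  # (16, k-1) int
    compartment: str
    n_reads: int
    n_excluded: int = 0

    @property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=0, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)

    @property
    def positions(self) -> np.ndarray:
        """5'-anchored pair start positions, 1..k-1."""
        return np.arange(1, self.k)

    @property
    def offsets_3prime(self) -> np.ndarray:
        """3'-offset of each pair's 3' base: pair starting at i has it at k-i."""
        return self.k - self.positions

    @property
    def pyrimidine_fraction(self) -> np.ndarray:
        """Aggregate CC+CT+TC+TT frequency per position."""
        idx = [_PAIR_INDEX[p] for p in PYRIMIDINE_PAIRS]
        return self.frequencies[idx].sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies.T, columns=list(DINUCLEOTIDES))
        df.insert(0, "offset_3prime", self.offsets_3prime)
        df.insert(0, "position", self.positions)
        df["pyrimidine_pair"] = self.pyrimidine_fraction
        return df


def _sequences(reads: Iterable[AlignedRead | str]) -> list[str]:
    return [r if isinstance(r, str) else r.sequence for r in reads]


def nucleotide_matrix(reads: Sequence[AlignedRead | str],
                      length: int) -> PositionCompositionMatrix:
    """Count bases per 5'-position across reads of one fixed length."""
    counts = np.zeros((4, length), dtype=int)
    n_used = n_excluded = 0
    for seq in _sequences(reads):
        if len(seq) != length:
            raise ValueError(
                f"mixed lengths: expected {length}, got {len(seq)}")
        if "N" in seq:
            n_excluded += 1
            continue
        for i, b in enumerate(seq):
            counts[_BASE_INDEX[b], i] += 1
        n_used += 1
    return PositionCompositionMatrix(length, counts, n_used, n_excluded)


def nucleotide_matrices(reads: Sequence[AlignedRead],
                        lengths: Iterable[int] = range(19, 31),
                        ) -> dict[int, PositionCompositionMatrix]:
    """One composition matrix per read length (the 12 lengths 19..30)."""
    by_length: dict[int, list[AlignedRead]] = {}
    for r in reads:
        by_length.setdefault(len(r), []).append(r)
    return {L: nucleotide_matrix(by_length.get(L, []), L) for L in lengths
            if by_length.get(L)}


def dinucleotide_profile(reads: Sequence[AlignedRead | str], k: int = 20,
                         compartment: str = "nuclear") -> DinucleotideProfile:
    """Adjacent-pair counts per position for reads trimmed to ``k`` nt."""
    counts = np.zeros((16, k - 1), dtype=int)
    n_used = n_excluded = 0
    for seq in _sequences(reads):
        if len(seq) != k:
            raise ValueError(f"read length {len(seq)} != trim length {k}")
        if "N" in seq:
            n_excluded += 1
            continue
        for i in range(k - 1):
            counts[_PAIR_INDEX[seq[i:i + 2]], i] += 1
        n_used += 1
    return DinucleotideProfile(k, counts, compartment, n_used, n_excluded)


def compartment_profiles(reads: Sequence[AlignedRead], k: int = 20,
                         mito_contigs: frozenset[str] | set[str] = MITO_CONTIGS,
                         ) -> dict[str, DinucleotideProfile]:
    """Split k-trimmed reads by contig into nuclear vs mitochondrial profiles."""
    nuclear = [r for r in reads if r.contig not in mito_contigs]
    mito = [r for r in reads if r.contig in mito_contigs]
    return {
        "nuclear": dinucleotide_profile(nuclear, k, "nuclear"),
        "mitochondrial": dinucleotide_profile(mito, k, "mitochondrial"),
    }


def pyrimidine_peak(profile: DinucleotideProfile, top: int = 2) -> list[int]:
    """The ``top`` 3'-offsets with the highest pyrimidine-pair frequency."""
    frac = profile.pyrimidine_fraction
    order = np.argsort(frac)[::-1][:top]
    return sorted(int(profile.offsets_3prime[i]) for i in order)


def flatness(profile: DinucleotideProfile) -> float:
    """Max/median pyrimidine-pair frequency; ~1 for signature-free reads."""
    frac = profile.pyrimidine_fraction
    med = float(np.median(frac))
    if med == 0:
        return float("inf")
    return float(frac.max()) / med
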