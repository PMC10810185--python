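"""Synthetic genomes, genes, and excised-oligo libraries with known truth.

The generator emulates the statistical structure a quantitative
excision-repair sequencing (qXR-Seq) experiment produces:

* excised oligomers 19-30 nt long whose 3' ends carry a pyrimidine
  dinucleotide ("dipyrimidine") at a fixed small offset from the 3' terminus
  -- the footprint the 3' incision of nucleotide excision repair leaves 5-6 nt
  downstream of the UV photoproduct;
* a programmable transcribed-strand bias inside genes (transcription-coupled
  repair): an oligo from the transcribed strand maps antisense to the gene;
* a mitochondrial contig ("chrM") that never carries the damage signature,
  mirroring the use of mitochondrial reads as a specificity control;
* spike-in libraries from a second genome mixed in at a fixed read amount;
* serial dilutions of a base library for calibration-curve fitting;
* adaptor-ligated, partially duplicated raw reads, so the trimming and
  deduplication stages have real work to do.

Every emitted read is recorded in a truth manifest (one row per raw read,
duplicates included), which downstream tests use as the oracle.

Damage-offset convention: an offset ``o`` is the 1-based distance of the
dinucleotide's 3' base from the read's 3' terminus; the pair therefore
occupies 3'-offsets ``o+1`` (5' base) and ``o``.  The defaults {5, 6} put the
aggregate pyrimidine-dinucleotide peak at 3'-offsets 5-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignedRead, GeneModel, RawRead, revcomp

BASES = np.array(list("ACGT"))
PYRIMIDINES = ("C", "T")

#: 3' adaptor appended to every simulated raw read (Illumina TruSeq small-RNA).
DEFAULT_ADAPTOR = "TGGAATTCTCGGGTGCCAAGG"


def _uniform_weights(lo: int, hi: int) -> dict[int, float]:
    n = hi - lo + 1
    return {length: 1.0 / n for length in range(lo, hi + 1)}


@dataclass
class SimulationParams:
    """Knobs of the synthetic experiment; defaults are the study conditions.

    ``tcr_ratio`` is the TS:NTS odds for signal reads inside genes (TS = read
    strand opposite the gene's annotated strand).  ``signal_fraction`` is the
    fraction of non-mitochondrial reads carrying the damage signature.
    ``damage_offset_weights`` are weights over the 3'-offset of the planted
    dinucleotide's 3' base.  ``dilutions`` default to the printed worm series
    1 ... 1/10,000.
    """

    seed: int = 0
    genome_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 100_000, "chrM": 8_000})
    gc: float = 0.5
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (800, 4_000)
    intergenic_gap: int = 400
    n_reads: int = 6_000
    length_weights: Mapping[int, float] = field(
        default_factory=lambda: _uniform_weights(19, 30))
    signal_fraction: float = 0.85
    damage_offset_weights: Mapping[int, float] = field(
        default_factory=lambda: {5: 0.5, 6: 0.5})
    tcr_ratio: float = 4.0
    mito_fraction: float = 0.05
    spike_reads: int = 1_000
    adaptor: str = DEFAULT_ADAPTOR
    duplicate_rate: float = 0.1
    dilutions: Sequence[float] = (1.0, 0.1, 0.01, 1e-3, 1e-4)

    def __post_init__(self) -> None:
        for name in ("signal_fraction", "mito_fraction", "duplicate_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must lie in (0,1)")
        if self.tcr_ratio < 1.0:
            raise ValueError("tcr_ratio is a TS:NTS odds and must be >= 1")
        for name in ("length_weights", "damage_offset_weights"):
            w = getattr(self, name)
            total = float(sum(w.values()))
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} must sum to 1, got {total}")
        if any(not (0.0 < d <= 1.0) for d in self.dilutions):
            raise ValueError("dilutions must lie in (0,1]")
        if not self.adaptor:
            raise ValueError("adaptor must be non-empty")


@dataclass
class SimulatedLibrary:
    """A simulated library: truth-aligned reads, raw reads, and the manifest.

    ``manifest`` has one row per *raw* read (duplicates included) with
    columns: read_id, origin (gene id / 'intergenic' / 'chrM'), strand_class
    (TS/NTS/NA), signal (bool), damage_offset (-1 for background), contig,
    start, end, strand, sequence (adaptor-free), is_duplicate.
    """

    sample_id: str
    aligned: list[AlignedRead]
    raw: list[RawRead]
    manifest: pd.DataFrame
    true_amount: float = 1.0


def make_genome(params: SimulationParams,
                rng: np.random.Generator | None = None) -> dict[str, str]:
    """Generate random contigs; deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    for contig, size in params.genome_sizes.items():
        if size < 1_000:
            raise ValueError(f"contig {contig!r}: size {size} < 1 kb minimum")
    p_gc = params.gc
    probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
    genome = {}
    for contig, size in params.genome_sizes.items():
        genome[contig] = "".join(BASES[rng.choice(4, size=size, p=probs)])
    return genome


def make_genes(genome: Mapping[str, str], params: SimulationParams,
               rng: np.random.Generator | None = None,
               flank: int = 2_000,
               max_attempts: int = 20_000) -> list[GeneModel]:
    """Place non-overlapping genes on the nuclear contigs.

    Genes keep at least ``intergenic_gap`` bp edge-to-edge separation and at
    least ``flank`` bp clearance from contig edges (so metagene flanks are
    never truncated).  Lengths are uniform over ``gene_length_range``; the
    default range straddles the species selection thresholds so gene
    selection has both outcomes to exercise.
    """
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    nuclear = [c for c in genome if c != "chrM"]
    if not nuclear:
        raise ValueError("no nuclear contig to place genes on")
    sizes = np.array([len(genome[c]) for c in nuclear], dtype=float)
    lo, hi = params.gene_length_range
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in nuclear}
    genes: list[tuple[str, int, int, str]] = []
    attempts = 0
    while len(genes) < params.n_genes:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not pack {params.n_genes} genes of {lo}-{hi} bp with "
                f"{params.intergenic_gap} bp gaps into the genome")
        contig = nuclear[rng.choice(len(nuclear), p=sizes / sizes.sum())]
        length = int(rng.integers(lo, hi + 1))
        limit = len(genome[contig]) - flank - length
        if limit <= flank:
            continue
        start = int(rng.integers(flank, limit))
        end = start + length
        # separation check: reject if any existing gene is closer than the gap
        ok = not any(start - params.intergenic_gap < e and
                     s < end + params.intergenic_gap
                     for s, e in placed[contig])
        if not ok:
            continue
        placed[contig].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((contig, start, end, strand))
    genes.sort(key=lambda g: (g[0], g[1]))
    return [GeneModel(c, s, e, st, f"g{i + 1:04d}")
            for i, (c, s, e, st) in enumerate(genes)]


def _read_oriented(genome: Mapping[str, str], contig: str, start: int,
                   end: int, strand: str) -> str:
    seq = genome[contig][start:end]
    return revcomp(seq) if strand == "-" else seq


def _has_planted_pair(seq: str, offset: int) -> bool:
    # pair bases sit at 3'-offsets offset+1 (5' base) and offset (3' base)
    n = len(seq)
    return seq[n - offset - 1] in PYRIMIDINES and seq[n - offset] in PYRIMIDINES


def simulate_library(genome: Mapping[str, str], genes: Sequence[GeneModel],
                     params: SimulationParams,
                     rng: np.random.Generator | None = None,
                     sample_id: str = "lib") -> SimulatedLibrary:
    """Simulate one excised-oligo library with a truth manifest.

    Each read is first assigned to the mitochondrial compartment with
    probability ``mito_fraction`` (always background there); otherwise it is
    a signal read with probability ``signal_fraction`` (placed inside a gene,
    strand odds ``tcr_ratio`` TS:NTS, carrying the planted dipyrimidine) or a
    background read at a uniform nuclear position.  Signal placement is by
    rejection sampling on the unmodified genome, so read sequences always
    agree with their coordinates.
    """
    rng = np.random.default_rng(params.seed + 2) if rng is None else rng
    lengths = np.array(sorted(params.length_weights))
    length_p = np.array([params.length_weights[l] for l in lengths])
    offsets = np.array(sorted(params.damage_offset_weights))
    offset_p = np.array([params.damage_offset_weights[o] for o in offsets])
    nuclear = [c for c in genome if c != "chrM"]
    nuc_sizes = np.array([len(genome[c]) for c in nuclear], dtype=float)
    p_ts = params.tcr_ratio / (params.tcr_ratio + 1.0)
    has_mito = "chrM" in genome

    aligned: list[AlignedRead] = []
    rows: list[dict] = []

    for i in range(params.n_reads):
        read_id = f"{sample_id}_r{i + 1:06d}"
        length = int(rng.choice(lengths, p=length_p))
        if has_mito and rng.random() < params.mito_fraction:
            contig = "chrM"
            start = int(rng.integers(0, len(genome[contig]) - length))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = _read_oriented(genome, contig, start, start + length, strand)
            origin, strand_class, signal, offset = "chrM", "NA", False, -1
        elif genes and rng.random() < params.signal_fraction:
            gene = genes[int(rng.integers(len(genes)))]
            is_ts = rng.random() < p_ts
            strand = ("-" if gene.strand == "+" else "+") if is_ts else gene.strand
            offset = int(rng.choice(offsets, p=offset_p))
            for _ in range(2_000):
                start = int(rng.integers(gene.start, gene.end - length + 1))
                seq = _read_oriented(genome, gene.contig, start,
                                     start + length, strand)
                if _has_planted_pair(seq, offset):
                    break
            else:  # pragma: no cover - astronomically unlikely on random genomes
                raise RuntimeError("could not place a signal read; gene too "
                                   "pyrimidine-poor")
            contig = gene.contig
            origin = gene.gene_id
            strand_class = "TS" if is_ts else "NTS"
            signal = True
        else:
            contig = nuclear[rng.choice(len(nuclear), p=nuc_sizes / nuc_sizes.sum())]
            start = int(rng.integers(0, len(genome[contig]) - length))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = _read_oriented(genome, contig, start, start + length, strand)
            origin, strand_class, signal, offset = "intergenic", "NA", False, -1

        aligned.append(AlignedRead(contig, start, start + length, strand, seq,
                                   read_id=read_id, sample_id=sample_id))
        rows.append(dict(read_id=read_id, origin=origin,
                         strand_class=strand_class, signal=signal,
                         damage_offset=offset, contig=contig, start=start,
                         end=start + length, strand=strand, sequence=seq,
                         is_duplicate=False))

    raw = [RawRead(r["read_id"], r["sequence"] + params.adaptor) for r in rows]

    # PCR-style duplicates: each read re-emitted once with prob duplicate_rate
    n_base = len(rows)
    for j in range(n_base):
        if rng.random() < params.duplicate_rate:
            dup = dict(rows[j])
            dup["read_id"] = rows[j]["read_id"] + "_dup"
            dup["is_duplicate"] = True
            rows.append(dup)
            raw.append(RawRead(dup["read_id"], dup["sequence"] + params.adaptor))

    manifest = pd.DataFrame(rows)
    return SimulatedLibrary(sample_id, aligned, raw, manifest)


def make_spikein_series(base: SimulatedLibrary, spike: SimulatedLibrary,
                        dilutions: Sequence[float], spike_reads: int,
                        rng: np.random.Generator | None = None,
                        ) -> list[SimulatedLibrary]:
    """Mix serial dilutions of ``base`` with a constant amount of ``spike``.

    Library ``d`` keeps each base raw read independently with probability
    ``d`` (Binomial thinning) and adds exactly ``spike_reads`` reads sampled
    without replacement from the spike library.  The truth manifest records
    ``d`` as the library's true relative amount.
    """
    if not base.raw:
        raise ValueError("empty base library")
    if spike_reads > len(spike.raw):
        raise ValueError(
            f"spike library has {len(spike.raw)} reads < spike_reads={spike_reads}")
    rng = np.random.default_rng(0) if rng is None else rng
    series = []
    for d in dilutions:
        if not (0.0 < d <= 1.0):
            raise ValueError(f"dilution {d} outside (0,1]")
        keep = rng.random(len(base.raw)) < d
        raw = [r for r, k in zip(base.raw, keep) if k]
        base_rows = base.manifest.loc[keep].copy()
        spike_idx = rng.choice(len(spike.raw), size=spike_reads, replace=False)
        spike_idx.sort()
        raw += [spike.raw[int(j)] for j in spike_idx]
        spike_rows = spike.manifest.iloc[spike_idx].copy()
        manifest = pd.concat([base_rows, spike_rows], ignore_index=True)
        sample_id = f"{base.sample_id}_d{d:g}"
        series.append(SimulatedLibrary(sample_id, [], raw, manifest,
                                       true_amount=d))
    return series
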