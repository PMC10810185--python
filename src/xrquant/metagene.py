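"""Strand-resolved unit-gene repair profiles (transcription-coupled repair).

Genes passing length/isolation thresholds are divided into 150 bins: 25
flank bins of 80 bp (2 kb) upstream of the TSS, 100 body bins covering
TSS..TES, and 25 flank bins of 80 bp downstream of the TES.  Bin order is
always 5'->3' of the *gene*, so bin 1 is 2 kb upstream of the TSS on either
genomic strand.

Strand convention -- stated loudly because it reverses naive intuition: an
excised oligomer released from the transcribed strand (TS) maps *antisense*
to the gene annotation.  A read whose strand is opposite the gene's strand
therefore counts as TS, and a same-strand read as NTS (the ``-S`` / ``-s``
convention of strand-aware interval intersection).

Per-bin values are RPKM (reads per kb of bin per million total filtered
reads of the sample), averaged over the selected genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignedRead, GeneModel

N_FLANK_BINS = 25
N_BODY_BINS = 100
FLANK_BIN_BP = 80
N_BINS = 2 * N_FLANK_BINS + N_BODY_BINS  # 150
FLANK_BP = N_FLANK_BINS * FLANK_BIN_BP   # 2000

#: Gene-selection thresholds (min gene length, min distance to nearest gene).
SPECIES_GENE_PARAMS = {
    "human": (5_000, 5_000),
    "worm": (1_000, 500),
    "fly": (1_000, 100),
}


@dataclass(frozen=True)
class GeneSelectionParams:
    min_length: int
    min_distance: int

    @classmethod
    def for_species(cls, species: str) -> "GeneSelectionParams":
        try:
            return cls(*SPECIES_GENE_PARAMS[species])
        except KeyError:
            raise ValueError(f"no gene-selection preset for {species!r}") from None


@dataclass
class GeneSelection:
    kept: list[GeneModel]
    #: genes kept but whose 2 kb flank runs off a contig edge (truncated)
    truncated_ids: set[str] = field(default_factory=set)


def select_genes(genes: Sequence[GeneModel], params: GeneSelectionParams,
                 contig_lengths: Mapping[str, int] | None = None,
                 ) -> GeneSelection:
    """Keep genes >= min_length whose nearest neighbour is >= min_distance away.

    Distance is edge-to-edge and strand-ignorant; overlapping genes have
    distance zero and are dropped whenever min_distance > 0.  Genes whose
    2 kb flank would cross a contig edge are kept but flagged.
    """
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    kept, truncated = [], set()
    for contig, group in by_contig.items():
        group = sorted(group, key=lambda g: (g.start, g.end))
        for i, g in enumerate(group):
            if g.length < params.min_length:
                continue
            dist = min(
                (max(0, h.start - g.end) if h.start >= g.start
                 else max(0, g.start - h.end))
                for j, h in enumerate(group) if j != i
            ) if len(group) > 1 else None
            if dist is not None and dist < params.min_distance:
                continue
            kept.append(g)
            if contig_lengths is not None:
                clen = contig_lengths[contig]
                if g.start < FLANK_BP or clen - g.end < FLANK_BP:
                    truncated.add(g.gene_id)
    kept.sort(key=lambda g: (g.contig, g.start))
    return GeneSelection(kept, truncated)


@dataclass
class BinnedGene:
    gene: GeneModel
    #: 150 genomic (start, end) intervals in gene-oriented bin order 1..150
    intervals: list[tuple[int, int]]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([e - s for s, e in self.intervals])


def bin_gene(gene: GeneModel, contig_length: int) -> BinnedGene:
    """Divide a gene plus 2 kb flanks into 150 gene-oriented bins.

    Body bins are an integer partition of the gene length into 100 near-equal
    parts, the remainder going to the *last* r bins (in gene orientation) so
    the partition is deterministic.  Flank bins crossing a contig edge are
    clipped (possibly to zero length).  Genes shorter than 100 bp cannot be
    binned.
    """
    if gene.length < N_BODY_BINS:
        raise ValueError(
            f"gene {gene.gene_id!r} is {gene.length} bp < {N_BODY_BINS} bp minimum")
    base, rem = divmod(gene.length, N_BODY_BINS)
    body_sizes = [base] * (N_BODY_BINS - rem) + [base + 1] * rem

    def clip(s: int, e: int) -> tuple[int, int]:
        s2, e2 = max(0, min(s, contig_length)), max(0, min(e, contig_length))
        return (s2, max(s2, e2))

    intervals: list[tuple[int, int]] = []
    if gene.strand == "+":
        for b in range(N_FLANK_BINS):
            s = gene.start - FLANK_BP + b * FLANK_BIN_BP
            intervals.append(clip(s, s + FLANK_BIN_BP))
        pos = gene.start
        for size in body_sizes:
            intervals.append((pos, pos + size))
            pos += size
        for b in range(N_FLANK_BINS):
            s = gene.end + b * FLANK_BIN_BP
            intervals.append(clip(s, s + FLANK_BIN_BP))
    else:
        for b in range(N_FLANK_BINS):
            e = gene.end + FLANK_BP - b * FLANK_BIN_BP
            intervals.append(clip(e - FLANK_BIN_BP, e))
        pos = gene.end
        for size in body_sizes:
            intervals.append((pos - size, pos))
            pos -= size
        for b in range(N_FLANK_BINS):
            e = gene.start - b * FLANK_BIN_BP
            intervals.append(clip(e - FLANK_BIN_BP, e))
    return BinnedGene(gene, intervals)


def bin_genes(genes: Sequence[GeneModel],
              contig_lengths: Mapping[str, int]) -> list[BinnedGene]:
    return [bin_gene(g, contig_lengths[g.contig]) for g in genes]


@dataclass
class BinCounts:
    """Per-gene per-bin TS and NTS read counts plus bin lengths."""

    gene_ids: list[str]
    ts: np.ndarray          # (n_genes, 150) int
    nts: np.ndarray         # (n_genes, 150) int
    bin_lengths: np.ndarray  # (n_genes, 150) int
    gene_strands: list[str]

    def totals(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "ts": self.ts.sum(axis=1),
            "nts": self.nts.sum(axis=1),
        })

    def swap_strands(self) -> "BinCounts":
        """The counts that result from flipping every gene's annotated strand.

        Flipping a gene's strand exchanges TS and NTS *and* reverses its bin
        order (bin 1 is defined relative to the TSS, which moves to the other
        end).
        """
        return BinCounts(self.gene_ids, self.nts[:, ::-1].copy(),
                         self.ts[:, ::-1].copy(),
                         self.bin_lengths[:, ::-1].copy(),
                         ["-" if s == "+" else "+" for s in self.gene_strands])


def assign_reads(reads: Sequence[AlignedRead],
                 binned_genes: Sequence[BinnedGene],
                 min_overlap_fraction: float = 0.5) -> BinCounts:
    """Count reads into gene bins, strand-resolved.

    A read counts in a bin iff the overlap is at least
    ``min_overlap_fraction`` of the *read* length (fraction-of-read, the
    ``-F`` convention); every satisfying (read, bin) pair is counted, so one
    read can hit at most floor(1/f) bins.  Reads antisense to the gene count
    as TS, sense reads as NTS.
    """
    if not (0.0 < min_overlap_fraction <= 1.0):
        raise ValueError("min_overlap_fraction must lie in (0,1]")
    n = len(binned_genes)
    ts = np.zeros((n, N_BINS), dtype=int)
    nts = np.zeros((n, N_BINS), dtype=int)
    lengths = np.zeros((n, N_BINS), dtype=int)

    # per-contig sorted span index over gene footprints (gene +/- flank)
    spans: dict[str, list[tuple[int, int, int]]] = {}
    for gi, bg in enumerate(binned_genes):
        lengths[gi] = bg.lengths
        starts = [s for s, e in bg.intervals if e > s]
        ends = [e for s, e in bg.intervals if e > s]
        if not starts:
            continue
        spans.setdefault(bg.gene.contig, []).append(
            (min(starts), max(ends), gi))
    for contig in spans:
        spans[contig].sort()

    for read in reads:
        contig_spans = spans.get(read.contig)
        if not contig_spans:
            continue
        need = min_overlap_fraction * len(read)
        for span_start, span_end, gi in contig_spans:
            if span_start >= read.end:
                break
            if span_end <= read.start:
                continue
            bg = binned_genes[gi]
            target = ts if read.strand != bg.gene.strand else nts
            for bi, (bs, be) in enumerate(bg.intervals):
                ov = min(read.end, be) - max(read.start, bs)
                if ov >= need and ov > 0:
                    target[gi, bi] += 1
    return BinCounts([bg.gene.gene_id for bg in binned_genes], ts, nts,
                     lengths, [bg.gene.strand for bg in binned_genes])


def rank_genes_ts_nts(counts: BinCounts, n: int = 5_000) -> list[str]:
    """Top ``n`` gene ids by (TS+1)/(NTS+1) on the reference (WT) sample.

    Ties break by total read count (descending) then gene id, so the ranking
    is deterministic even on all-zero counts.
    """
    tot_ts = counts.ts.sum(axis=1)
    tot_nts = counts.nts.sum(axis=1)
    ratio = (tot_ts + 1.0) / (tot_nts + 1.0)
    order = sorted(range(len(counts.gene_ids)),
                   key=lambda i: (-ratio[i], -(tot_ts[i] + tot_nts[i]),
                                  counts.gene_ids[i]))
    return [counts.gene_ids[i] for i in order[:min(n, len(order))]]


def profile_rpkm(counts: BinCounts, total_mapped_reads: int,
                 gene_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Mean per-bin TS and NTS RPKM over (a subset of) the counted genes.

    RPKM for gene g, bin b = count / (bin_length_kb * total_mapped_reads/1e6);
    ``total_mapped_reads`` is the sample's full count of aligned,
    length- and damage-filtered reads.  Zero-length (edge-clipped) bins
    contribute zero.  Returns a 150-row frame with columns bin, ts, nts.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    if gene_ids is None:
        mask = np.ones(len(counts.gene_ids), dtype=bool)
    else:
        wanted = set(gene_ids)
        mask = np.array([g in wanted for g in counts.gene_ids])
    if not mask.any():
        raise ValueError("no genes selected for the profile")
    scale = total_mapped_reads / 1e6
    kb = counts.bin_lengths[mask] / 1_000.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ts = np.where(kb > 0, counts.ts[mask] / (kb * scale), 0.0)
        nts = np.where(kb > 0, counts.nts[mask] / (kb * scale), 0.0)
    return pd.DataFrame({
        "bin": np.arange(1, N_BINS + 1),
        "ts": ts.mean(axis=0),
        "nts": nts.mean(axis=0),
    })


def body_ts_nts_ratio(profile: pd.DataFrame) -> float:
    """Summed TS / summed NTS RPKM over the 100 gene-body bins."""
    body = profile.iloc[N_FLANK_BINS:N_FLANK_BINS + N_BODY_BINS]
    nts_sum = float(body["nts"].sum())
    if nts_sum == 0:
        return float("inf")
    return float(body["ts"].sum()) / nts_sum
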