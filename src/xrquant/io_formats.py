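"""Readers and writers for the plain-text formats the pipeline touches.

All genomic intervals are 0-based half-open (the BED convention), everywhere,
including in memory.  Read sequences are stored *read-oriented* (5'->3' of the
excised oligomer): for a minus-strand read the stored sequence is the reverse
complement of the reference slice.  All 3'-end positional logic downstream
(damage offsets, length trimming) is defined on the oligo, not the reference,
and relies on this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A malformed external file; the message names the offending line."""


def revcomp(sequence: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RawRead:
    """An unaligned sequencing read, possibly adaptor-bearing and duplicated."""

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedRead:
    """A mapped excised oligo.

    ``sequence`` is the read as sequenced, i.e. the reverse complement of the
    reference slice when ``strand`` is '-'.
    """

    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    read_id: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"read {self.read_id!r}: bad interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id!r}: bad strand {self.strand!r}")
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: interval length {self.end - self.start} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene; the source of TS/NTS orientation."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id!r}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Sample:
    """One row of the sample sheet."""

    sample_id: str
    species: str
    spike_species: str
    uv: bool
    genotype: str
    dilution: float | None = None
    input_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.dilution is not None and not (0.0 < self.dilution <= 1.0):
            raise ValueError(
                f"sample {self.sample_id!r}: dilution must lie in (0,1]"
            )
        if self.input_scale <= 0:
            raise ValueError(f"sample {self.sample_id!r}: input_scale must be > 0")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (id, uppercased sequence).

    Raises :class:`FormatError` naming the line for malformed headers,
    illegal characters, or duplicate ids.  An empty file yields [].
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def _flush(line_no: int) -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: record {name!r} has no sequence "
                              f"(before line {line_no})")
        records.append((name, seq))

    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush(line_no)
                header = line[1:].split()
                if not header:
                    raise FormatError(f"{path}:{line_no}: empty FASTA header")
                name = header[0]
                if name in seen:
                    raise FormatError(f"{path}:{line_no}: duplicate id {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{line_no}: sequence before first '>' header"
                    )
                seq = line.strip().upper()
                bad = set(seq) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}:{line_no}: illegal characters {sorted(bad)}"
                    )
                chunks.append(seq)
        _flush(line_no=-1)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[RawRead]:
    """Read FASTQ reads (qualities are discarded; this assay does not use them)."""
    reads = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate read id {rec.id!r}")
        seen.add(rec.id)
        reads.append(RawRead(rec.id, str(rec.seq).upper()))
    return reads


def read_raw_reads(path: str | Path) -> list[RawRead]:
    """Read raw reads from FASTA or FASTQ, sniffed from the first character."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return [RawRead(name, seq) for name, seq in read_fasta(path)]


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def _parse_bed6_row(path, line_no: int, line: str) -> tuple[str, int, int, str, str, str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise FormatError(
            f"{path}:{line_no}: expected 6 BED columns, got {len(fields)}"
        )
    chrom, start_s, end_s, name, score, strand = fields[:6]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise FormatError(f"{path}:{line_no}: non-integer coordinates") from None
    if start < 0 or start >= end:
        raise FormatError(f"{path}:{line_no}: bad interval [{start},{end})")
    if strand not in ("+", "-"):
        raise FormatError(f"{path}:{line_no}: unknown strand symbol {strand!r}")
    return chrom, start, end, name, score, strand


def read_bed6_reads(
    path: str | Path,
    genome: Mapping[str, str] | None = None,
    sequences: Mapping[str, str] | None = None,
    sample_id: str = "",
) -> list[AlignedRead]:
    """Read aligned reads from BED6.

    Sequences come either from ``sequences`` (read id -> read-oriented
    sequence, e.g. a reads FASTA) or are reconstructed from ``genome``
    (contig -> sequence), reverse-complemented on the minus strand.
    """
    if genome is None and sequences is None:
        raise ValueError("read_bed6_reads needs a genome or a sequence mapping")
    reads = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = _parse_bed6_row(
                path, line_no, line)
            if sequences is not None:
                if name not in sequences:
                    raise FormatError(
                        f"{path}:{line_no}: no sequence for read id {name!r}")
                seq = sequences[name].upper()
            else:
                if chrom not in genome:
                    raise FormatError(
                        f"{path}:{line_no}: contig {chrom!r} not in genome")
                ref = genome[chrom]
                if end > len(ref):
                    raise FormatError(
                        f"{path}:{line_no}: interval end {end} beyond contig "
                        f"{chrom!r} length {len(ref)}")
                seq = ref[start:end].upper()
                if strand == "-":
                    seq = revcomp(seq)
            try:
                reads.append(AlignedRead(chrom, start, end, strand, seq,
                                         read_id=name, sample_id=sample_id))
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from None
    return reads


def write_bed6_reads(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.read_id}\t0\t{r.strand}\n")


def read_bed6_genes(path: str | Path) -> list[GeneModel]:
    genes = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = _parse_bed6_row(
                path, line_no, line)
            if name in seen:
                raise FormatError(f"{path}:{line_no}: duplicate gene id {name!r}")
            seen.add(name)
            genes.append(GeneModel(chrom, start, end, strand, name))
    return genes


def write_bed6_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Sample sheet and profile tables
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "yes", "uv", "y"}
_FALSY = {"0", "false", "no", "nouv", "n", ""}


def read_sample_sheet(path: str | Path) -> list[Sample]:
    """Read a TSV sample sheet.

    Required columns: sample_id, species, spike_species, uv, genotype.
    Optional: dilution (blank for non-calibration samples), input_scale.
    Exactly one spike species is allowed per experiment.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["sample_id", "species", "spike_species", "uv", "genotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing sample sheet columns {missing}")
    samples = []
    for i, row in df.iterrows():
        uv_raw = str(row["uv"]).strip().lower()
        if uv_raw in _TRUTHY:
            uv = True
        elif uv_raw in _FALSY:
            uv = False
        else:
            raise FormatError(f"{path}: row {i + 2}: uninterpretable uv value "
                              f"{row['uv']!r}")
        dilution = None
        if "dilution" in df.columns and str(row["dilution"]).strip():
            dilution = float(row["dilution"])
        scale = 1.0
        if "input_scale" in df.columns and str(row["input_scale"]).strip():
            scale = float(row["input_scale"])
        samples.append(Sample(row["sample_id"], row["species"],
                              row["spike_species"], uv, row["genotype"],
                              dilution, scale))
    spikes = {s.spike_species for s in samples}
    if len(spikes) != 1:
        raise FormatError(
            f"{path}: exactly one spike species per experiment, got {sorted(spikes)}")
    return samples


def write_profile_tsv(profile: pd.DataFrame, path: str | Path) -> None:
    """Write a profile table; round-trips through read_profile_tsv to 1e-9."""
    profile.to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
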