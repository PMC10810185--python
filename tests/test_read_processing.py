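"""Trim / dedup / align / length operations and their pipeline composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xrquant.io_formats import AlignedRead, RawRead, revcomp
from xrquant.read_processing import (GenomeIndex, LengthRange,
                                     SPECIES_LENGTH_RANGES, align_exact,
                                     auto_select_range, dedup, filter_length,
                                     process_library, trim_5prime_to,
                                     trim_adaptor)
from xrquant.synthetic_data import SimulationParams, make_genes, make_genome, \
    simulate_library

ADAPTOR = "TGGAATTCTCGGGTGCCAAGG"


class TestTrimAdaptor:
    def test_removes_full_adaptor_suffix(self):
        read = RawRead("r", "ACGTACGT" + ADAPTOR)
        assert trim_adaptor(read, ADAPTOR).sequence == "ACGTACGT"

    def test_read_without_adaptor_passes_unchanged(self):
        read = RawRead("r", "ACGACGACGACG")
        assert trim_adaptor(read, ADAPTOR).sequence == "ACGACGACGACG"

    def test_read_equal_to_adaptor_is_discarded(self):
        assert trim_adaptor(RawRead("r", ADAPTOR), ADAPTOR) is None

    def test_partial_adaptor_prefix_at_3prime_end_is_removed(self):
        read = RawRead("r", "ACGTACGTACGT" + ADAPTOR[:6])
        assert trim_adaptor(read, ADAPTOR).sequence == "ACGTACGTACGT"

    def test_suffix_below_min_overlap_is_kept(self):
        read = RawRead("r", "ACGACGACGAC" + ADAPTOR[:2])
        assert trim_adaptor(read, ADAPTOR, min_overlap=3).sequence == read.sequence


class TestDedup:
    def test_keeps_first_occurrence_per_sequence(self):
        reads = [RawRead("a", "ACGT"), RawRead("b", "ACGT"), RawRead("c", "AAAA")]
        out = dedup(reads)
        assert [r.read_id for r in out] == ["a", "c"]

    def test_idempotent(self):
        reads = [RawRead("a", "ACGT"), RawRead("c", "AAAA")]
        assert dedup(dedup(reads)) == dedup(reads)

    def test_count_matches_distinct_manifest_sequences(self):
        p = SimulationParams(seed=11, genome_sizes={"chr1": 30_000},
                             n_genes=5, gene_length_range=(1_200, 2_500),
                             n_reads=1_000, duplicate_rate=0.3,
                             mito_fraction=0.0)
        genome = make_genome(p)
        lib = simulate_library(genome, make_genes(genome, p), p)
        expected = lib.manifest["sequence"].nunique()
        assert len(dedup(lib.raw)) == expected


@pytest.fixture(scope="module")
def repeat_genome():
    rng = np.random.default_rng(99)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5_000)])
    # plant an exact repeat so the multi-hit rule is exercised
    seq = seq[:1_000] + seq[2_000:2_025] + seq[1_025:]
    return {"chrT": seq}


class TestAlignExact:
    def test_forward_unique_hit(self, repeat_genome):
        query = repeat_genome["chrT"][100:125]
        (hit,), stats = align_exact([RawRead("r", query)], repeat_genome)
        assert (hit.contig, hit.start, hit.end, hit.strand) == ("chrT", 100, 125, "+")
        assert stats["unique"] == 1

    def test_reverse_complement_maps_to_minus_strand(self, repeat_genome):
        query = revcomp(repeat_genome["chrT"][100:125])
        (hit,), _ = align_exact([RawRead("r", query)], repeat_genome)
        assert (hit.start, hit.end, hit.strand) == (100, 125, "-")
        assert hit.sequence == query  # stored read-oriented

    def test_repeated_sequence_is_dropped(self, repeat_genome):
        query = repeat_genome["chrT"][1_000:1_025]  # planted twice
        hits, stats = align_exact([RawRead("r", query)], repeat_genome)
        assert hits == [] and stats["multi"] == 1

    def test_absent_sequence_is_dropped(self, repeat_genome):
        hits, stats = align_exact([RawRead("r", "A" * 25)], repeat_genome)
        assert hits == [] and stats["unmapped"] == 1


class TestLengthOps:
    @staticmethod
    def reads_of_lengths(lengths):
        rng = np.random.default_rng(5)
        out = []
        for i, L in enumerate(lengths):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
            out.append(AlignedRead("chr1", 100, 100 + L, "+", seq, read_id=f"r{i}"))
        return out

    def test_human_range_keeps_24_to_30(self):
        reads = self.reads_of_lengths(range(18, 32))
        kept = filter_length(reads, LengthRange(*SPECIES_LENGTH_RANGES["human"]))
        assert sorted(len(r) for r in kept) == list(range(24, 31))

    def test_full_assay_range_spans_12_lengths(self):
        reads = self.reads_of_lengths(range(18, 32))
        kept = filter_length(reads, LengthRange(19, 30))
        assert len({len(r) for r in kept}) == 12

    def test_empty_input_passes_through(self):
        assert filter_length([], LengthRange(19, 30)) == []

    def test_trim_keeps_3prime_terminal_bases(self):
        (read,) = self.reads_of_lengths([27])
        (out,) = trim_5prime_to([read], k=20)
        assert out.sequence == read.sequence[-20:]

    def test_trim_interval_plus_strand(self):
        seq = "ACGTACGTACGTACGTACGTACGTACG"  # 27 nt
        plus = AlignedRead("c", 100, 127, "+", seq, read_id="p")
        (out,) = trim_5prime_to([plus], 20)
        assert (out.start, out.end) == (107, 127)

    def test_trim_interval_minus_strand(self):
        seq = "ACGTACGTACGTACGTACGTACGTACG"
        minus = AlignedRead("c", 100, 127, "-", seq, read_id="m")
        (out,) = trim_5prime_to([minus], 20)
        assert (out.start, out.end) == (100, 120)

    def test_trim_five_prime_anchor_keeps_leading_bases(self):
        seq = "ACGTACGTACGTACGTACGTACGTACG"
        plus = AlignedRead("c", 100, 127, "+", seq, read_id="p")
        (out,) = trim_5prime_to([plus], 20, anchor="five_prime")
        assert (out.start, out.end) == (100, 120)
        assert out.sequence == seq[:20]

    def test_trim_at_exact_length_is_identity(self):
        (read,) = self.reads_of_lengths([20])
        assert trim_5prime_to([read], 20) == [read]

    def test_trim_rejects_short_reads(self):
        (read,) = self.reads_of_lengths([19])
        with pytest.raises(ValueError, match="shorter than"):
            trim_5prime_to([read], 20)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(21, 30), st.integers(1, 20))
    def test_trim_preserves_every_3prime_offset(self, length, offset):
        rng = np.random.default_rng(length * 31 + offset)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
        read = AlignedRead("c", 0, length, "+", seq, read_id="r")
        (out,) = trim_5prime_to([read], 20)
        assert out.sequence[20 - offset] == seq[length - offset]


class TestAutoSelectRange:
    DEFAULT = LengthRange(20, 28)

    @staticmethod
    def library(signal_lengths, background_lengths, n_per_length=200, seed=21):
        """Reads with planted offset-5/6 pairs at some lengths, random at others."""
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        reads = []
        i = 0
        for L in signal_lengths:
            for _ in range(n_per_length):
                seq = list("".join(bases[rng.integers(0, 4, L)]))
                seq[L - 5] = "T"
                seq[L - 6] = "C"
                reads.append(AlignedRead("chr1", 0, L, "+", "".join(seq),
                                         read_id=f"s{i}"))
                i += 1
        for L in background_lengths:
            for _ in range(n_per_length):
                # purine-only: no pyrimidine pair anywhere
                seq = "".join(np.array(list("AG"))[rng.integers(0, 2, L)])
                reads.append(AlignedRead("chr1", 0, L, "+", seq,
                                         read_id=f"b{i}"))
                i += 1
        return reads

    def test_signal_restricted_to_24_30_selects_that_range(self):
        reads = self.library(range(24, 31), range(19, 24))
        selected, scores = auto_select_range(reads, self.DEFAULT)
        assert (selected.lo, selected.hi) == (24, 30)

    def test_uniform_signal_selects_full_range(self):
        reads = self.library(range(19, 31), [])
        selected, _ = auto_select_range(reads, self.DEFAULT)
        assert (selected.lo, selected.hi) == (19, 30)

    def test_background_only_falls_back_to_default(self, std_genome):
        p = SimulationParams(seed=31, signal_fraction=0.0, n_reads=3_000,
                             genome_sizes={"chr1": 30_000},
                             n_genes=4, gene_length_range=(1_200, 2_500),
                             mito_fraction=0.0)
        genome = make_genome(p)
        lib = simulate_library(genome, make_genes(genome, p), p)
        selected, _ = auto_select_range(lib.aligned, self.DEFAULT)
        assert selected == self.DEFAULT

    def test_sparse_data_falls_back_to_default(self):
        reads = self.library(range(24, 31), [], n_per_length=10)
        selected, _ = auto_select_range(reads, self.DEFAULT)
        assert selected == self.DEFAULT


class TestPipelineComposition:
    def test_recovers_99pct_of_in_range_signal_reads(self, std_library,
                                                     std_index, std_params):
        result = process_library(std_library.raw, std_index,
                                 std_params.adaptor, LengthRange(20, 28))
        truth = std_library.manifest.query(
            "signal and not is_duplicate and 20 <= end - start <= 28")
        wanted = set(map(tuple, truth[["contig", "start", "end", "strand"]]
                         .itertuples(index=False)))
        got = {(r.contig, r.start, r.end, r.strand) for r in result.reads
               if len(r) == r.end - r.start}
        # compare on the untrimmed coordinates: reconstruct from trim-to-20
        full = {(r.contig, r.start, r.end, r.strand) for r in result.reads}
        recovered = sum(1 for (c, s, e, st_) in wanted
                        if ((c, e - 20, e, st_) in full if st_ == "+"
                            else (c, s, s + 20, st_) in full))
        assert recovered / len(wanted) >= 0.99

    def test_stage_counts_never_increase(self, std_library, std_index,
                                         std_params):
        result = process_library(std_library.raw, std_index,
                                 std_params.adaptor, LengthRange(20, 28))
        counts = [n for _, n in result.report]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
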