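"""Gene selection, 150-bin scheme, strand-resolved counting and RPKM profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from xrquant.io_formats import AlignedRead, GeneModel
from xrquant.metagene import (BinCounts, GeneSelectionParams, N_BINS,
                              assign_reads, bin_gene, bin_genes,
                              body_ts_nts_ratio, profile_rpkm,
                              rank_genes_ts_nts, select_genes)
from xrquant.synthetic_data import SimulationParams, make_genes, make_genome, \
    simulate_library


def gene(start, end, strand="+", gene_id="g", contig="chr1"):
    return GeneModel(contig, start, end, strand, gene_id)


class TestSelectGenes:
    def test_close_pair_is_dropped_entirely(self):
        genes = [gene(10_000, 16_000, gene_id="a"),
                 gene(16_400, 22_000, gene_id="b")]  # 400 bp apart
        sel = select_genes(genes, GeneSelectionParams(1_000, 500))
        assert sel.kept == []

    def test_isolated_long_gene_passes_human_thresholds(self):
        genes = [gene(100_000, 106_000, gene_id="a")]
        sel = select_genes(genes, GeneSelectionParams(5_000, 5_000))
        assert [g.gene_id for g in sel.kept] == ["a"]

    def test_edge_proximal_gene_is_kept_but_flagged(self):
        genes = [gene(500, 2_000, gene_id="edge")]
        sel = select_genes(genes, GeneSelectionParams(1_000, 500),
                           contig_lengths={"chr1": 50_000})
        assert [g.gene_id for g in sel.kept] == ["edge"]
        assert sel.truncated_ids == {"edge"}

    def test_matches_quadratic_distance_oracle_on_random_fixture(self):
        rng = np.random.default_rng(42)
        genes = []
        pos = 3_000
        for i in range(50):
            length = int(rng.integers(300, 3_000))
            genes.append(gene(pos, pos + length, gene_id=f"g{i:02d}"))
            pos += length + int(rng.integers(50, 2_000))
        params = GeneSelectionParams(1_000, 500)

        def oracle():
            kept = []
            for g in genes:
                if g.end - g.start < params.min_length:
                    continue
                dmin = min(
                    (h.start - g.end if h.start >= g.end else
                     g.start - h.end if h.end <= g.start else 0)
                    for h in genes if h is not g)
                if dmin >= params.min_distance:
                    kept.append(g.gene_id)
            return kept

        sel = select_genes(genes, params)
        assert [g.gene_id for g in sel.kept] == oracle()
        assert 0 < len(sel.kept) < 50  # the fixture exercises both outcomes


class TestBinGene:
    def test_plus_strand_first_body_bin_starts_at_tss(self):
        bg = bin_gene(gene(10_000, 11_000, "+"), 100_000)
        assert bg.intervals[25] == (10_000, 10_010)
        assert bg.intervals[0] == (8_000, 8_080)     # 2 kb upstream
        assert bg.intervals[149] == (12_920, 13_000)  # 2 kb downstream

    def test_minus_strand_reverses_genomic_order(self):
        bg = bin_gene(gene(10_000, 11_000, "-"), 100_000)
        assert bg.intervals[25] == (10_990, 11_000)  # bin 26 abuts the TSS
        assert bg.intervals[0] == (12_920, 13_000)   # bin 1 upstream of TSS

    def test_remainder_goes_to_the_last_body_bins(self):
        bg = bin_gene(gene(0 + 5_000, 5_000 + 1_003, "+"), 100_000)
        body = [e - s for s, e in bg.intervals[25:125]]
        assert body == [10] * 97 + [11] * 3
        assert sum(body) == 1_003

    def test_partition_sums_to_gene_length_for_random_lengths(self, rng):
        for length in rng.integers(100, 60_000, size=1_000):
            bg = bin_gene(gene(70_000, 70_000 + int(length), "+"), 10**9)
            body = bg.lengths[25:125]
            assert body.sum() == length
            assert body.max() - body.min() <= 1

    def test_sub_100bp_gene_rejected(self):
        with pytest.raises(ValueError, match="minimum"):
            bin_gene(gene(1_000, 1_099), 100_000)


class TestAssignReads:
    @pytest.fixture()
    def binned(self):
        return bin_genes([gene(10_000, 11_000, "+", "g1")], {"chr1": 100_000})

    @staticmethod
    def read(start, end, strand):
        return AlignedRead("chr1", start, end, strand, "A" * (end - start),
                           read_id="r")

    def test_sense_read_in_flank_counts_as_nts(self, binned):
        counts = assign_reads([self.read(8_010, 8_030, "+")], binned)
        assert counts.nts[0, 0] == 1 and counts.ts.sum() == 0

    def test_antisense_read_counts_as_ts(self, binned):
        counts = assign_reads([self.read(8_010, 8_030, "-")], binned)
        assert counts.ts[0, 0] == 1 and counts.nts.sum() == 0

    def test_even_split_read_reaches_both_bins_at_half_overlap(self, binned):
        # body bins are 10 bp; a 20-nt read split 10/10 meets the >= 0.5
        # fraction in both bins (the bedtools -F convention is inclusive)
        counts = assign_reads([self.read(10_010, 10_030, "+")], binned)
        assert counts.nts[0, 26] == 1 and counts.nts[0, 27] == 1

    def test_uneven_split_counts_only_the_majority_bin(self, binned):
        counts = assign_reads([self.read(10_013, 10_033, "+")], binned)
        assert counts.nts[0].sum() == 1

    def test_total_counts_bounded_by_reads_times_two(self, std_genome):
        p = SimulationParams(seed=29, n_reads=1_500,
                             genome_sizes={"chr1": 50_000}, n_genes=8,
                             gene_length_range=(1_200, 3_000),
                             mito_fraction=0.0)
        genome = make_genome(p)
        genes = make_genes(genome, p)
        lib = simulate_library(genome, genes, p)
        binned = bin_genes(genes, {c: len(s) for c, s in genome.items()})
        counts = assign_reads(lib.aligned, binned, 0.5)
        assert counts.ts.sum() + counts.nts.sum() <= len(lib.aligned) * 2

    def test_flipping_gene_strands_swaps_ts_and_nts_exactly(self):
        # gene lengths divisible by 100 keep the body-bin partition
        # flip-symmetric (the remainder rule is gene-oriented)
        p = SimulationParams(seed=30, n_reads=1_000,
                             genome_sizes={"chr1": 50_000}, n_genes=6,
                             gene_length_range=(2_000, 2_000),
                             mito_fraction=0.0)
        genome = make_genome(p)
        genes = make_genes(genome, p)
        lib = simulate_library(genome, genes, p)
        contig_lengths = {c: len(s) for c, s in genome.items()}
        flipped = [GeneModel(g.contig, g.start, g.end,
                             "-" if g.strand == "+" else "+", g.gene_id)
                   for g in genes]
        counts = assign_reads(lib.aligned, bin_genes(genes, contig_lengths))
        swapped = assign_reads(lib.aligned, bin_genes(flipped, contig_lengths))
        np.testing.assert_array_equal(swapped.ts, counts.swap_strands().ts)
        np.testing.assert_array_equal(swapped.nts, counts.swap_strands().nts)


class TestRankGenes:
    @staticmethod
    def counts_from_totals(totals):
        n = len(totals)
        ts = np.zeros((n, N_BINS), dtype=int)
        nts = np.zeros((n, N_BINS), dtype=int)
        for i, (t, v) in enumerate(totals.values()):
            ts[i, 50], nts[i, 50] = t, v
        return BinCounts(list(totals), ts, nts,
                         np.full((n, N_BINS), 10), ["+"] * n)

    def test_orders_by_pseudocounted_ratio(self):
        counts = self.counts_from_totals(
            {"a": (9, 0), "b": (3, 0), "c": (1, 0)})  # ratios 10, 4, 2
        assert rank_genes_ts_nts(counts, 2) == ["a", "b"]

    def test_all_zero_counts_break_ties_by_gene_id(self):
        counts = self.counts_from_totals({"z": (0, 0), "a": (0, 0), "m": (0, 0)})
        assert rank_genes_ts_nts(counts, 3) == ["a", "m", "z"]

    def test_tcr_cohort_is_enriched_at_the_top(self):
        """Genes read with TS bias outrank unbiased ones (hypergeometric)."""
        rng = np.random.default_rng(77)
        totals = {}
        for i in range(15):  # TCR cohort: TS:NTS odds 4
            n = 200
            ts = rng.binomial(n, 0.8)
            totals[f"tcr{i:02d}"] = (ts, n - ts)
        for i in range(15):  # neutral cohort
            n = 200
            ts = rng.binomial(n, 0.5)
            totals[f"flat{i:02d}"] = (ts, n - ts)
        counts = self.counts_from_totals(totals)
        top = rank_genes_ts_nts(counts, 15)
        k = sum(1 for g in top if g.startswith("tcr"))
        p = sps.hypergeom.sf(k - 1, 30, 15, 15)
        assert p < 1e-6


class TestProfileRpkm:
    def test_arithmetic_80bp_bin(self):
        counts = BinCounts(["g"], np.zeros((1, N_BINS), int),
                           np.zeros((1, N_BINS), int),
                           np.full((1, N_BINS), 80), ["+"])
        counts.ts[0, 0] = 5
        profile = profile_rpkm(counts, 1_000_000)
        assert profile["ts"][0] == pytest.approx(62.5)  # 5 / (0.08 * 1)

    def test_invariant_to_uniform_depth_scaling(self):
        rng = np.random.default_rng(3)
        ts = rng.integers(0, 20, (4, N_BINS))
        nts = rng.integers(0, 20, (4, N_BINS))
        lengths = np.full((4, N_BINS), 50)
        a = profile_rpkm(BinCounts(list("abcd"), ts, nts, lengths, ["+"] * 4),
                         10_000)
        b = profile_rpkm(BinCounts(list("abcd"), ts * 3, nts * 3, lengths,
                                   ["+"] * 4), 30_000)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_total_rejected(self):
        counts = BinCounts(["g"], np.zeros((1, N_BINS), int),
                           np.zeros((1, N_BINS), int),
                           np.full((1, N_BINS), 80), ["+"])
        with pytest.raises(ValueError, match="positive"):
            profile_rpkm(counts, 0)

    def test_recovers_simulated_tcr_ratio(self):
        p = SimulationParams(seed=31, n_reads=3_000, signal_fraction=1.0,
                             mito_fraction=0.0, tcr_ratio=4.0,
                             genome_sizes={"chr1": 60_000}, n_genes=10,
                             gene_length_range=(1_500, 3_500),
                             intergenic_gap=600)
        genome = make_genome(p)
        genes = make_genes(genome, p)
        lib = simulate_library(genome, genes, p)
        binned = bin_genes(genes, {c: len(s) for c, s in genome.items()})
        counts = assign_reads(lib.aligned, binned)
        profile = profile_rpkm(counts, len(lib.aligned))
        ratio = body_ts_nts_ratio(profile)
        # delta method on the odds at p=0.8; halve n since RPKM averaging
        # weights genes unequally
        sd = 25 * np.sqrt(0.8 * 0.2 / (len(lib.manifest) / 2))
        assert abs(ratio - 4.0) < 3 * sd
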