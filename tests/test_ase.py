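"""SNP calling, allele-depth counting, and the binomial imbalance test."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import binomial_two_sided_half, naive_allele_totals
from trioexpress.ase import (
    AseDirection,
    GeneAseResult,
    aggregate_and_filter,
    binomial_exact_test,
    call_snps,
    compare_conditions,
    count_allele_depths,
    test_allelic_imbalance,
)
from trioexpress.core_io import AlignedRead, SnpRecord, TrioValidationError


class TestCallSnps:
    def test_single_difference(self):
        low = {"tx1": "A" * 44 + "A" + "A" * 5}
        high = {"tx1": "A" * 44 + "G" + "A" * 5}
        snps, skipped = call_snps(low, high, gene_map={"tx1": "g1"})
        assert snps == [SnpRecord("tx1", "g1", 45, "A", "G")]
        assert skipped == 0

    def test_identical_pair_yields_nothing(self):
        snps, skipped = call_snps({"tx1": "ACGT"}, {"tx1": "ACGT"})
        assert snps == [] and skipped == 0

    def test_ambiguous_base_skipped_and_counted(self):
        snps, skipped = call_snps({"tx1": "ANGT"}, {"tx1": "AAGT"})
        assert snps == [] and skipped == 1

    def test_length_mismatch_names_the_pair(self):
        with pytest.raises(TrioValidationError, match="tx1"):
            call_snps({"tx1": "ACGT"}, {"tx1": "ACG"})

    def test_case_insensitive(self):
        snps, _ = call_snps({"tx1": "acgt"}, {"tx1": "aCtt"})
        assert snps == [SnpRecord("tx1", "tx1", 3, "G", "T")]


def _reads_at_snp(bases, start=41, snp_pos=45, prefix="r"):
    """Reads of length 10 covering position 45, with the given base there."""
    reads = []
    for i, base in enumerate(bases):
        seq = list("CCCCCCCCCC")
        seq[snp_pos - start] = base
        reads.append(AlignedRead(f"{prefix}{i}", "tx1", start, "".join(seq)))
    return reads


class TestCountAlleleDepths:
    SNP = SnpRecord("tx1", "g1", 45, "A", "G")

    def test_depths_follow_base_matching(self):
        reads = _reads_at_snp(["G"] * 7 + ["A"] * 3)
        depths = count_allele_depths(reads, reads, [self.SNP])
        assert depths[0].depth_low == 3
        assert depths[0].depth_high == 7

    def test_read_ending_before_snp_contributes_nothing(self):
        read = AlignedRead("r0", "tx1", 35, "C" * 10)  # covers 35-44, SNP at 45
        depths = count_allele_depths([read], [read], [self.SNP])
        assert (depths[0].depth_low, depths[0].depth_high, depths[0].depth_other) == (0, 0, 0)

    def test_third_base_counts_as_other(self):
        reads = _reads_at_snp(["T"])
        depths = count_allele_depths(reads, reads, [self.SNP])
        assert depths[0].depth_other == 2  # covering in both files, matching neither
        assert depths[0].depth_low == 0 and depths[0].depth_high == 0

    def test_duplicate_read_id_counted_once_per_file(self):
        reads = _reads_at_snp(["A"]) * 2  # same read id twice
        depths = count_allele_depths(reads, [], [self.SNP])
        assert depths[0].depth_low == 1

    def test_snp_on_transcript_without_reads_gets_zero_depths(self):
        other = SnpRecord("tx9", "g9", 5, "C", "T")
        depths = count_allele_depths([], [], [other])
        assert (depths[0].depth_low, depths[0].depth_high) == (0, 0)

    def test_allele_swap_symmetry(self):
        """Swapping the allele labels and the two read sets swaps the depths
        and leaves the test p-value unchanged."""
        reads_low_file = _reads_at_snp(["A"] * 3 + ["G"] * 7, prefix="a")
        reads_high_file = _reads_at_snp(["A"] * 3 + ["G"] * 7, prefix="b")
        fwd = count_allele_depths(reads_low_file, reads_high_file, [self.SNP])[0]
        swapped_snp = SnpRecord("tx1", "g1", 45, "G", "A")
        rev = count_allele_depths(reads_high_file, reads_low_file, [swapped_snp])[0]
        assert (fwd.depth_low, fwd.depth_high) == (rev.depth_high, rev.depth_low)
        p_fwd = binomial_exact_test(fwd.depth_high, fwd.depth_low + fwd.depth_high)
        p_rev = binomial_exact_test(rev.depth_high, rev.depth_low + rev.depth_high)
        assert p_fwd == p_rev


class TestAggregateAndFilter:
    def _depth(self, gene, low, high, pos=10):
        from trioexpress.ase import AlleleDepth

        snp = SnpRecord(f"{gene}_t", gene, pos, "A", "G")
        return AlleleDepth(snp=snp, depth_low=low, depth_high=high, depth_other=0)

    def test_mean_depth_arithmetic(self):
        # two SNPs, 15 + 14 informative reads => mean 14.5 > 10
        depths = [self._depth("g1", 7, 8, pos=10), self._depth("g1", 6, 8, pos=20)]
        results, exclusions = aggregate_and_filter(depths)
        assert len(results) == 1
        assert results[0].mean_depth_per_snp == pytest.approx(14.5)
        assert (results[0].total_low, results[0].total_high) == (13, 16)
        assert not exclusions

    def test_mean_exactly_at_cutoff_excluded(self):
        """'Greater than 10' is strict: a mean of exactly 10 fails the filter."""
        depths = [self._depth("g1", 5, 5)]
        results, exclusions = aggregate_and_filter(depths)
        assert results == []
        assert exclusions["below_min_mean_depth"] == 1

    def test_gene_without_snps_absent(self):
        results, _ = aggregate_and_filter([])
        assert results == []

    def test_other_depth_does_not_rescue_the_filter(self):
        from trioexpress.ase import AlleleDepth

        snp = SnpRecord("g1_t", "g1", 10, "A", "G")
        depths = [AlleleDepth(snp=snp, depth_low=4, depth_high=4, depth_other=50)]
        results, exclusions = aggregate_and_filter(depths)
        assert results == []


class TestBinomialExactTest:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (7, 10, 0.34375),   # sum of C(10,j)/2^10 over pmf(j) <= pmf(7)
            (5, 10, 1.0),       # the most likely outcome sums everything
            (15, 30, 1.0),
        ],
    )
    def test_reference_values(self, k, n, expected):
        assert binomial_exact_test(k, n) == pytest.approx(expected, abs=1e-12)

    def test_extreme_outcome_tiny_p(self):
        assert binomial_exact_test(0, 20) == pytest.approx(2 * 0.5**20, rel=1e-9)
        assert binomial_exact_test(0, 20) < 0.001

    def test_invalid_inputs_rejected(self):
        with pytest.raises(TrioValidationError):
            binomial_exact_test(-1, 10)
        with pytest.raises(TrioValidationError):
            binomial_exact_test(11, 10)
        with pytest.raises(TrioValidationError):
            binomial_exact_test(0, 0)

    @settings(derandomize=True, max_examples=150)
    @given(data=st.data())
    def test_symmetry_and_oracle_agreement(self, data):
        n = data.draw(st.integers(min_value=1, max_value=200))
        k = data.draw(st.integers(min_value=0, max_value=n))
        p = binomial_exact_test(k, n)
        assert p == pytest.approx(binomial_exact_test(n - k, n), rel=1e-12)
        assert p == pytest.approx(float(binomial_two_sided_half(k, n)), rel=1e-9)


class TestAllelicImbalance:
    def _pre(self, gene, low, high):
        return GeneAseResult(
            gene_id=gene, n_snps=1, total_low=low, total_high=high,
            mean_depth_per_snp=float(low + high),
        )

    def test_strong_imbalance_detected_with_direction(self):
        results, _ = test_allelic_imbalance([self._pre("g1", 3, 27)])
        (res,) = results
        assert res.p_value < 0.001
        assert res.significant
        assert res.direction is AseDirection.HIGH_HIGHER

    def test_balanced_counts_p_one(self):
        results, _ = test_allelic_imbalance([self._pre("g1", 15, 15)])
        assert results[0].p_value == pytest.approx(1.0)
        assert results[0].direction is AseDirection.BALANCED

    def test_mild_imbalance_not_significant(self):
        results, _ = test_allelic_imbalance([self._pre("g1", 14, 16)])
        assert not results[0].significant
        exact = float(binomial_two_sided_half(16, 30))
        assert results[0].p_value == pytest.approx(exact, rel=1e-9)

    def test_zero_informative_reads_excluded(self):
        results, exclusions = test_allelic_imbalance([self._pre("g1", 0, 0)])
        assert results == []
        assert exclusions["zero_informative_reads"] == 1

    def test_bh_flag_adjusts_and_is_more_conservative(self):
        pre = [self._pre(f"g{i}", 10, 30) for i in range(5)] + [
            self._pre("g_null", 20, 20)
        ]
        raw, _ = test_allelic_imbalance(pre, bh=False)
        adj, _ = test_allelic_imbalance(pre, bh=True)
        assert sum(r.significant for r in adj) <= sum(r.significant for r in raw)
        assert all(r.q_value >= r.p_value for r in adj)


class TestCompareConditions:
    def _res(self, gene, significant, direction=AseDirection.HIGH_HIGHER):
        return GeneAseResult(
            gene_id=gene, n_snps=1, total_low=10, total_high=30,
            mean_depth_per_snp=40.0, p_value=0.01 if significant else 0.8,
            significant=significant,
            direction=direction if significant else AseDirection.BALANCED,
        )

    def test_overlap_counts(self):
        a = [self._res("g1", True), self._res("g2", True), self._res("g3", False)]
        b = [self._res("g2", True), self._res("g3", True), self._res("g1", False)]
        overlap = compare_conditions(a, b)
        assert overlap["both"] == 1
        assert overlap["a_only"] == 1
        assert overlap["b_only"] == 1
        assert overlap["neither"] == 0

    def test_identical_inputs(self):
        a = [self._res("g1", True), self._res("g2", False)]
        overlap = compare_conditions(a, a)
        assert overlap["a_only"] == 0 and overlap["b_only"] == 0
        assert overlap["both"] == 1 and overlap["neither"] == 1
        assert overlap["both_same_direction"] == 1

    def test_disjoint_significance(self):
        a = [self._res(f"g{i}", i < 4) for i in range(9)]
        b = [self._res(f"g{i}", 4 <= i < 9) for i in range(9)]
        overlap = compare_conditions(a, b)
        assert overlap["both"] == 0
        assert overlap["a_only"] == 4 and overlap["b_only"] == 5


class TestEndToEndCounting:
    def test_full_chain_matches_naive_scan(self, noise_free_bundle):
        """call_snps -> count_allele_depths -> aggregate reproduces a
        brute-force scan over every read at every SNP."""
        b = noise_free_bundle
        gene_map = {tid: tid.rsplit("_t", 1)[0] for tid in b["low_tx"]}
        called, _ = call_snps(b["low_tx"], b["high_tx"], gene_map=gene_map)
        assert set(called) == set(b["snps"])
        depths = count_allele_depths(b["reads_low"], b["reads_high"], called)
        results, _ = aggregate_and_filter(depths, min_mean_depth=0.0)
        expected = naive_allele_totals(b["reads_low"], b["reads_high"], called)
        assert len(results) == len(expected)
        for res in results:
            assert res.total_low == expected[res.gene_id]["low"]
            assert res.total_high == expected[res.gene_id]["high"]
            assert res.n_snps == expected[res.gene_id]["n_snps"]
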