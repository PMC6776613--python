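"""Exact binomial MAF-shift tests, p-value adjustment, and enrichment summaries."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from itgh import (
    ValidationError,
    adjust_pvalues,
    binomial_shift_test,
    compare_paired,
    fisher_2x2,
    maf_concordance,
    ns_ratio,
    summarize_enrichment,
)
from itgh.dynamics import PairedComparison
from itgh.variants import VariantKey
from conftest import make_table


def binom_minlike_oracle(k, n, p0_frac):
    """Exhaustive enumeration with exact-rational tie decisions.

    Point probabilities are compared as exact fractions; the p-value sums the
    float pmf of the selected outcomes with an exactly-rounded sum.
    """
    q = 1 - p0_frac
    probs = [Fraction(math.comb(n, i)) * p0_frac**i * q ** (n - i) for i in range(n + 1)]
    selected = [i for i in range(n + 1) if probs[i] <= probs[k]]
    if len(selected) == n + 1:
        return 1.0
    return min(1.0, math.fsum(stats.binom.pmf(i, n, float(p0_frac)) for i in selected))


class TestBinomialShiftTest:
    def test_modal_outcome_gives_p_one(self):
        assert binomial_shift_test(5, 10, 0.5) == 1.0

    def test_symmetric_extreme_tail_closed_form(self):
        assert binomial_shift_test(0, 20, 0.5) == pytest.approx(2 * 0.5**20, rel=1e-12)

    def test_one_sided_extreme_under_asymmetric_null(self):
        # only k = 10 itself has point probability <= 0.2^10
        assert binomial_shift_test(10, 10, 0.2) == pytest.approx(0.2**10, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            binomial_shift_test(1, 10, 0.0)
        with pytest.raises(ValidationError):
            binomial_shift_test(11, 10, 0.5)

    def test_central_method_doubles_the_smaller_tail(self):
        p = binomial_shift_test(2, 30, 0.5, method="central")
        assert p == pytest.approx(2 * float(stats.binom.cdf(2, 30, 0.5)), rel=1e-12)
        assert binomial_shift_test(15, 30, 0.5, method="central") == 1.0

    @pytest.mark.parametrize("n", [1, 5, 12, 17])
    @pytest.mark.parametrize("p0", [Fraction(1, 10), Fraction(1, 4), Fraction(1, 2)])
    def test_equals_enumeration_oracle_small_grid(self, n, p0):
        for k in range(n + 1):
            assert binomial_shift_test(k, n, float(p0)) == binom_minlike_oracle(k, n, p0)

    def test_cross_check_against_scipy_binomtest(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.02, 0.98))
            ours = binomial_shift_test(k, n, p0)
            ref = stats.binomtest(k, n, p0).pvalue
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in ("bonferroni", "bh"):
            assert adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_bonferroni_multiplies_by_m(self):
        assert list(adjust_pvalues([0.01, 0.04], "bonferroni")) == [
            pytest.approx(0.02),
            pytest.approx(0.08),
        ]

    def test_bh_step_up_with_cumulative_minimum(self):
        assert list(adjust_pvalues([0.01, 0.02, 0.03], "bh")) == [pytest.approx(0.03)] * 3

    def test_ordering_bonferroni_geq_bh_geq_raw_and_capped(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 40)
        bonf = adjust_pvalues(p, "bonferroni")
        bh = adjust_pvalues(p, "bh")
        assert np.all(bonf >= bh - 1e-12) and np.all(bh >= p - 1e-12)
        assert np.all(bonf <= 1.0) and np.all(bh <= 1.0)


class TestComparePaired:
    def test_large_frequency_drop_is_enriched_in_a(self):
        a = make_table("A", [("1", 1, "A", "T", 50, 50, "nonsynonymous")])
        b = make_table("B", [("1", 1, "A", "T", 90, 10, "nonsynonymous")])
        (c,) = compare_paired(a, b, alpha=0.05)
        assert c.enriched_in == "A" and c.direction == "down_in_b"
        assert c.p_adj < 0.05

    def test_identical_counts_are_not_enriched(self):
        a = make_table("A", [("1", 1, "A", "T", 50, 50, "synonymous")])
        b = make_table("B", [("1", 1, "A", "T", 50, 50, "synonymous")])
        (c,) = compare_paired(a, b)
        assert c.enriched_in == "none" and c.direction == "none"

    def test_noncoding_excluded_unless_restriction_lifted(self):
        a = make_table("A", [("1", 1, "A", "T", 50, 50, "noncoding")])
        b = make_table("B", [("1", 1, "A", "T", 90, 10, "noncoding")])
        assert compare_paired(a, b, restrict_coding_splice=True) == []
        assert len(compare_paired(a, b, restrict_coding_splice=False)) == 1

    def test_reference_maf_of_one_is_untestable(self):
        a = make_table("A", [("1", 1, "A", "T", 0, 60, "synonymous")])
        b = make_table("B", [("1", 1, "A", "T", 30, 30, "synonymous")])
        assert compare_paired(a, b) == []

    def test_depth_filter_applies_to_both_samples(self):
        a = make_table("A", [("1", 1, "A", "T", 3, 3, "synonymous")])
        b = make_table("B", [("1", 1, "A", "T", 50, 50, "synonymous")])
        assert compare_paired(a, b, min_depth=10) == []

    def test_swap_symmetry_maps_enrichment_sides(self):
        rows_a = [("1", i, "A", "T", 80, 20, "nonsynonymous") for i in range(1, 6)]
        rows_b = [("1", i, "A", "T", 20, 80, "nonsynonymous") for i in range(1, 6)]
        a, b = make_table("A", rows_a), make_table("B", rows_b)
        fwd = {c.key: c.enriched_in for c in compare_paired(a, b)}
        rev = {c.key: c.enriched_in for c in compare_paired(b, a)}
        swap = {"A": "B", "B": "A", "none": "none"}
        assert rev == {k: swap[v] for k, v in fwd.items()}

    def test_zero_shared_variants_is_empty_not_error(self):
        a = make_table("A", [("1", 1, "A", "T", 50, 50, "synonymous")])
        b = make_table("B", [("2", 2, "C", "G", 50, 50, "synonymous")])
        assert compare_paired(a, b) == []


def _comp(i, enriched, effect):
    return PairedComparison(
        VariantKey("1", i, "A", "T"), 0.1, 0.3, 30, 100, 1e-4, 1e-3, "up_in_b", enriched, effect
    )


class TestEnrichmentSummaries:
    def test_ns_ratio_printed_examples(self):
        comps = [_comp(1 + i, "B", "nonsynonymous") for i in range(136)]
        comps += [_comp(200 + i, "B", "synonymous") for i in range(46)]
        comps += [_comp(300 + i, "A", "nonsynonymous") for i in range(8)]
        comps += [_comp(400 + i, "A", "synonymous") for i in range(5)]
        assert ns_ratio(comps, "B") == pytest.approx(2.96, abs=5e-3)
        assert ns_ratio(comps, "A") == pytest.approx(1.6)
        summary = summarize_enrichment(comps)
        assert summary.n_enriched == 195
        assert summary.fisher_p == pytest.approx(0.3305, abs=5e-4)

    def test_ns_ratio_unavailable_without_synonymous(self):
        comps = [_comp(1, "B", "nonsynonymous")]
        assert ns_ratio(comps, "B") is None

    def test_side_fractions_one_decimal_presentation(self):
        comps = [_comp(1 + i, "B", "nonsynonymous") for i in range(195)]
        comps += [_comp(500 + i, "A", "nonsynonymous") for i in range(15)]
        s = summarize_enrichment(comps)
        assert round(100 * s.side_fraction("B"), 1) == 92.9
        assert round(100 * s.side_fraction("A"), 1) == 7.1

    def test_zero_enriched_summary_degenerates(self):
        s = summarize_enrichment([])
        assert s.n_enriched == 0 and s.ns_ratio_a is None and s.ns_ratio_b is None


class TestFisher:
    def test_identical_rows_give_p_one(self):
        assert fisher_2x2([[3, 3], [3, 3]])[0] == pytest.approx(1.0)

    def test_diagonal_table_hypergeometric_enumeration(self):
        p, odds = fisher_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, rel=1e-9)
        assert odds == math.inf

    def test_all_zero_table_is_domain_error(self):
        with pytest.raises(ValidationError):
            fisher_2x2([[0, 0], [0, 0]])

    def test_sample_odds_ratio(self):
        _, odds = fisher_2x2([[10, 5], [2, 4]])
        assert odds == pytest.approx((10 * 4) / (5 * 2))


class TestMafConcordance:
    def test_perfect_agreement(self):
        rows = [("1", i, "A", "T", 100 - i * 10, i * 10) for i in range(1, 5)]
        a, b = make_table("A", rows), make_table("B", rows)
        r = maf_concordance(a, b)
        assert r.r == pytest.approx(1.0) and r.r2 == pytest.approx(1.0)

    def test_anti_identity(self):
        rows_a = [("1", i, "A", "T", 100 - i * 10, i * 10) for i in range(1, 4)]
        rows_b = [("1", i, "A", "T", i * 10, 100 - i * 10) for i in range(1, 4)]
        r = maf_concordance(make_table("A", rows_a), make_table("B", rows_b))
        assert r.r == pytest.approx(-1.0) and r.r2 == pytest.approx(1.0)

    def test_five_point_textbook_formula(self):
        xs = [0.1, 0.2, 0.3, 0.4, 0.5]
        ys = [0.15, 0.18, 0.35, 0.38, 0.45]
        rows_a = [("1", i + 1, "A", "T", int(100 - 100 * x), int(100 * x)) for i, x in enumerate(xs)]
        rows_b = [("1", i + 1, "A", "T", int(100 - 100 * y), int(100 * y)) for i, y in enumerate(ys)]
        r = maf_concordance(make_table("A", rows_a), make_table("B", rows_b))
        x, y = np.array(xs), np.array(ys)
        hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r.r == pytest.approx(hand, rel=1e-9)

    def test_too_few_shared_is_unavailable(self):
        rows = [("1", 1, "A", "T", 50, 50)]
        r = maf_concordance(make_table("A", rows), make_table("B", rows))
        assert not r.available and r.n == 1
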