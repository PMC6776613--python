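"""Subclonal dynamics between matched samples: exact binomial MAF-shift tests.

A variant shared between two matched samples (e.g. a tumor at diagnosis and
the residual tumor after neoadjuvant chemoradiation) is tested for a change in
mutant allele frequency with an exact binomial test: under the null, the alt
read count in sample B is Binomial(depth_B, p0) with p0 the observed MAF in
sample A. After multiple-testing correction across the tested set, variants
with adjusted p below alpha are classified as "enriched" in whichever sample
has the higher MAF. An excess of enriched, preferentially nonsynonymous
mutations in the post-treatment sample is the signature of clonal selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .variants import SampleTable, VariantKey, partition_variants

logger = logging.getLogger(__name__)

CODING_SPLICE = frozenset({"synonymous", "nonsynonymous", "splice"})

#: Relative slack when comparing point probabilities in the minimum-likelihood
#: two-sided test; wide enough to absorb float rounding of genuinely tied
#: outcomes (e.g. the symmetric pairs at p0 = 0.5), far below any real gap.
_TIE_REL_TOL = 1e-12


def binomial_shift_test(
    alt_b: int, depth_b: int, p0: float, method: str = "minlike"
) -> float:
    """Two-sided exact binomial p-value for alt_b successes in depth_b trials.

    ``minlike`` (default) is the minimum-likelihood method: the sum of the
    probabilities of every outcome whose point probability does not exceed
    that of the observed outcome. ``central`` doubles the smaller tail
    probability (capped at 1).
    """
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"p0 must be in (0, 1), got {p0}")
    if depth_b < 1:
        raise ValidationError(f"depth must be >= 1, got {depth_b}")
    if not 0 <= alt_b <= depth_b:
        raise ValidationError(f"alt count {alt_b} outside [0, {depth_b}]")

    if method == "central":
        lower = stats.binom.cdf(alt_b, depth_b, p0)
        upper = stats.binom.sf(alt_b - 1, depth_b, p0)
        return min(1.0, 2.0 * min(float(lower), float(upper)))
    if method != "minlike":
        raise ValidationError(f"unknown two-sided method {method!r}")

    pmf = stats.binom.pmf(np.arange(depth_b + 1), depth_b, p0)
    threshold = pmf[alt_b] * (1.0 + _TIE_REL_TOL)
    mask = pmf <= threshold
    if mask.all():  # observed outcome is (tied with) the mode: everything included
        return 1.0
    # fsum is exactly rounded, so the result is independent of summation order
    return min(1.0, math.fsum(pmf[mask]))


def adjust_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Multiplicity-adjusted p-values, order-preserving.

    ``bonferroni`` -> min(1, m * p_i); ``bh`` -> Benjamini-Hochberg step-up
    adjusted values (the FDR adjustment of R's p.adjust).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValidationError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


@dataclass
class PairedComparison:
    """Per-variant result of the MAF-shift test between matched samples A and B."""

    key: VariantKey
    maf_a: float
    maf_b: float
    alt_b: int
    depth_b: int
    p_raw: float
    p_adj: float
    direction: str  # up_in_b | down_in_b | none
    enriched_in: str  # A | B | none
    effect_class: str


@dataclass
class EnrichmentSummary:
    """Cohort-level counts of enriched mutations and the N/S selection contrast."""

    n_shared_tested: int
    n_enriched: int
    n_enriched_a: int
    n_enriched_b: int
    ns_ratio_a: float | None
    ns_ratio_b: float | None
    fisher_p: float
    fisher_odds: float

    @property
    def enriched_fraction(self) -> float | None:
        if self.n_shared_tested == 0:
            return None
        return self.n_enriched / self.n_shared_tested

    def side_fraction(self, side: str) -> float | None:
        """Fraction of enriched mutations on one side (A or B) of the pair."""
        if self.n_enriched == 0:
            return None
        n = self.n_enriched_a if side == "A" else self.n_enriched_b
        return n / self.n_enriched


def compare_paired(
    a: SampleTable,
    b: SampleTable,
    alpha: float = 0.05,
    method: str = "bonferroni",
    min_depth: int = 10,
    restrict_coding_splice: bool = True,
    test_method: str = "minlike",
) -> list[PairedComparison]:
    """Exact binomial MAF-shift tests over the variants shared by two samples.

    The null proportion p0 is A's observed MAF; the test statistic is B's
    (alt, depth). Only shared variants passing ``min_depth`` in both samples
    are tested; with ``restrict_coding_splice`` the tested set is further
    limited to coding and splice-site mutations (the set where selection is
    expected to act). Adjustment is applied across the tested set only.
    Variants whose A-side MAF is exactly 0 or 1 admit no two-sided binomial
    null and are excluded with a logged count.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    part = partition_variants(a, b)

    tested: list[tuple[VariantKey, object, object]] = []
    n_untestable = 0
    for key in part.shared:
        oa, ob = a.get(key), b.get(key)
        if oa.depth < min_depth or ob.depth < min_depth:
            continue
        effect = oa.effect_class if oa.effect_class != "unknown" else ob.effect_class
        if restrict_coding_splice and effect not in CODING_SPLICE:
            continue
        if oa.maf in (0.0, 1.0):
            n_untestable += 1
            continue
        tested.append((key, oa, ob))
    if n_untestable:
        logger.warning(
            "%s vs %s: %d shared variants untestable (reference-sample MAF exactly 0 or 1)",
            a.sample_id, b.sample_id, n_untestable,
        )
    if not tested:
        return []

    p_raw = [
        binomial_shift_test(ob.alt_count, ob.depth, oa.maf, test_method)
        for _, oa, ob in tested
    ]
    p_adj = adjust_pvalues(p_raw, method)

    results = []
    for (key, oa, ob), praw, padj in zip(tested, p_raw, p_adj):
        maf_a, maf_b = oa.maf, ob.maf
        if maf_b > maf_a:
            direction = "up_in_b"
        elif maf_b < maf_a:
            direction = "down_in_b"
        else:
            direction = "none"
        if padj < alpha and direction != "none":
            enriched_in = "B" if direction == "up_in_b" else "A"
        else:
            enriched_in = "none"
        effect = oa.effect_class if oa.effect_class != "unknown" else ob.effect_class
        results.append(
            PairedComparison(
                key, maf_a, maf_b, ob.alt_count, ob.depth,
                float(praw), float(padj), direction, enriched_in, effect,
            )
        )
    return results


def ns_ratio(comparisons, side: str) -> float | None:
    """Nonsynonymous/synonymous count ratio among variants enriched on one side.

    Returns None (unavailable) when no synonymous mutation is enriched there.
    """
    if side not in {"A", "B"}:
        raise ValidationError(f"side must be A or B, got {side!r}")
    n_ns = sum(1 for c in comparisons if c.enriched_in == side and c.effect_class == "nonsynonymous")
    n_s = sum(1 for c in comparisons if c.enriched_in == side and c.effect_class == "synonymous")
    if n_s == 0:
        return None
    return n_ns / n_s


def fisher_2x2(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 count table.

    Returns (p, sample odds ratio); the odds ratio is infinite when the
    off-diagonal product is zero. Two-sided p sums hypergeometric
    probabilities no larger than the observed table's.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValidationError("fisher_2x2 requires a non-negative 2x2 table")
    if t.sum() == 0:
        raise ValidationError("fisher_2x2: all-zero table")
    res = stats.fisher_exact(t, alternative=alternative)
    a, b2 = t[0]
    c, d = t[1]
    odds = math.inf if b2 * c == 0 else (a * d) / (b2 * c)
    return float(res.pvalue), odds


@dataclass
class ConcordanceResult:
    r: float
    r2: float
    n: int
    available: bool = True
    reason: str = ""


def maf_concordance(a: SampleTable, b: SampleTable, min_depth: int = 10) -> ConcordanceResult:
    """Pearson correlation of MAFs over variants shared by two samples.

    High concordance (r^2 near 1) means the two call sets sample the same
    allele-frequency structure — expected for germline pairs, degraded between
    pre- and post-treatment tumors when clonal composition shifts.
    """
    part = partition_variants(a, b)
    xs, ys = [], []
    for key in part.shared:
        oa, ob = a.get(key), b.get(key)
        if oa.depth >= min_depth and ob.depth >= min_depth:
            xs.append(oa.maf)
            ys.append(ob.maf)
    n = len(xs)
    if n < 3:
        return ConcordanceResult(float("nan"), float("nan"), n, False, "fewer than 3 shared variants")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return ConcordanceResult(float("nan"), float("nan"), n, False, "constant MAF vector")
    r = float(stats.pearsonr(xs, ys).statistic)
    return ConcordanceResult(r, r * r, n)


def summarize_enrichment(comparisons) -> EnrichmentSummary:
    """Counts, side-wise N/S ratios, and the Fisher N/S-by-side contrast.

    The Fisher table rows are (nonsynonymous, synonymous) counts for side B
    then side A — i.e. does the ratio of protein-altering to silent changes
    differ between the two directions of enrichment?
    """
    comparisons = list(comparisons)
    n_a = sum(1 for c in comparisons if c.enriched_in == "A")
    n_b = sum(1 for c in comparisons if c.enriched_in == "B")

    def _counts(side):
        ns = sum(1 for c in comparisons if c.enriched_in == side and c.effect_class == "nonsynonymous")
        s = sum(1 for c in comparisons if c.enriched_in == side and c.effect_class == "synonymous")
        return ns, s

    ns_b, s_b = _counts("B")
    ns_a, s_a = _counts("A")
    table = [[ns_b, s_b], [ns_a, s_a]]
    if ns_b + s_b + ns_a + s_a > 0:
        fisher_p, fisher_odds = fisher_2x2(table)
    else:
        fisher_p, fisher_odds = float("nan"), float("nan")
    return EnrichmentSummary(
        n_shared_tested=len(comparisons),
        n_enriched=n_a + n_b,
        n_enriched_a=n_a,
        n_enriched_b=n_b,
        ns_ratio_a=ns_ratio(comparisons, "A"),
        ns_ratio_b=ns_ratio(comparisons, "B"),
        fisher_p=fisher_p,
        fisher_odds=fisher_odds,
    )
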