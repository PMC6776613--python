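"""Cohort-level associations between MATH scores and clinical covariates.

Group contrasts use Wilcoxon rank tests: the unpaired rank-sum for
between-patient groupings (disease stage, nodal status) and the signed-rank
test for within-patient paired contrasts (pre- vs post-treatment). Continuous
covariates (copy-number burden, tumor purity) use Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Above this per-group size, or in the presence of ties, rank tests switch
#: from exact enumeration to the normal approximation with continuity
#: correction.
EXACT_N_MAX = 25


@dataclass
class GroupComparison:
    group_labels: tuple[str, str]
    n_per_group: tuple[int, int]
    medians: tuple[float, float]
    statistic: float
    p: float
    paired: bool
    method: str = ""  # exact | approx
    degenerate: bool = False


def compare_groups(
    values_a,
    values_b,
    paired: bool = False,
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-sided Wilcoxon contrast between two groups of scores.

    Unpaired: Mann-Whitney/Wilcoxon rank-sum, exact when both groups have at
    most 25 values and the pooled data have no ties, otherwise the normal
    approximation with continuity correction. Paired: Wilcoxon signed-rank on
    the non-zero differences under the same exact/approximate rule; when every
    difference is zero the result is degenerate with p = 1.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if paired and a.size != b.size:
        raise ValidationError(f"paired groups must have equal sizes ({a.size} vs {b.size})")
    if a.size < 1 or b.size < 1:
        raise ValidationError("each group needs at least one value")
    medians = (float(np.median(a)), float(np.median(b)))

    if paired:
        diffs = b - a
        nz = diffs[diffs != 0]
        if nz.size == 0:
            return GroupComparison(labels, (a.size, b.size), medians, 0.0, 1.0, True, "exact", True)
        ties = len(np.unique(np.abs(nz))) < nz.size
        method = "approx" if (nz.size > EXACT_N_MAX or ties) else "exact"
        res = stats.wilcoxon(nz, correction=(method == "approx"), method=method)
        return GroupComparison(
            labels, (a.size, b.size), medians, float(res.statistic), float(res.pvalue), True, method
        )

    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    method = "asymptotic" if (a.size > EXACT_N_MAX or b.size > EXACT_N_MAX or ties) else "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return GroupComparison(
        labels,
        (a.size, b.size),
        medians,
        float(res.statistic),
        float(res.pvalue),
        False,
        "approx" if method == "asymptotic" else "exact",
    )


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    available: bool = True
    reason: str = ""


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch ({x.size} vs {y.size})")
    if x.size < 3:
        return CorrelationResult(float("nan"), float("nan"), int(x.size), False, "fewer than 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(float("nan"), float("nan"), int(x.size), False, "constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def _normalize_stage(value: str) -> str:
    """Collapse e.g. 'Stage IIA' / 'iii' to a bare numeral I..IV."""
    s = str(value).strip().upper()
    if s.startswith("STAGE"):
        s = s[5:].strip()
    s = s.rstrip("ABC")
    return s if s in {"I", "II", "III", "IV"} else "NA"


def _normalize_nodal(value: str) -> str:
    s = str(value).strip().upper()
    s = s.rstrip("ABC")
    # accept e.g. N1MI -> N1
    if len(s) >= 2 and s[0] == "N" and s[1] in "012":
        return s[:2]
    return "NA"


def associate_math(math_table: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """Association report linking per-sample MATH scores to clinical metadata.

    Runs the stage contrast (I+II vs III+IV), the nodal contrast (N0 vs
    N1+N2), and Pearson correlations of MATH with CNV count and purity.
    Between-patient groupings use the unpaired rank-sum test: cohort samples
    come from independent patients, so a paired test is not applicable there
    (the report header notes this). Tests whose metadata column is absent or
    insufficient are reported as skipped with a reason.
    """
    if "sample_id" not in metadata.columns:
        raise ValidationError("metadata must carry a sample_id column")
    merged = math_table.loc[math_table["flag"] == ""].merge(metadata, on="sample_id", how="inner")
    if merged.empty:
        raise ValidationError("no overlapping sample ids between MATH table and metadata")
    merged = merged.sort_values("sample_id").reset_index(drop=True)

    report: dict = {
        "n_samples": int(len(merged)),
        "note": (
            "between-patient groupings (stage, nodal) use the unpaired Wilcoxon "
            "rank-sum test; the signed-rank test is reserved for within-patient "
            "paired contrasts"
        ),
        "tests": {},
    }

    def _group_test(name, column, normalize, low, high, labels):
        if column not in merged.columns:
            report["tests"][name] = {"skipped": f"column {column!r} absent"}
            return
        groups = merged[column].map(normalize)
        va = merged.loc[groups.isin(low), "math_score"]
        vb = merged.loc[groups.isin(high), "math_score"]
        if va.empty or vb.empty:
            report["tests"][name] = {"skipped": "a group is empty after normalization"}
            return
        gc = compare_groups(va, vb, paired=False, labels=labels)
        report["tests"][name] = asdict(gc)

    _group_test("stage", "stage", _normalize_stage, {"I", "II"}, {"III", "IV"}, ("I+II", "III+IV"))
    _group_test("nodal", "nodal", _normalize_nodal, {"N0"}, {"N1", "N2"}, ("N0", "N1+N2"))

    for name, column in (("cnv", "cnv_count"), ("purity", "purity")):
        if column not in merged.columns:
            report["tests"][name] = {"skipped": f"column {column!r} absent"}
            continue
        sub = merged[["math_score", column]].dropna()
        sub = sub[pd.to_numeric(sub[column], errors="coerce").notna()]
        cr = correlate(sub["math_score"], pd.to_numeric(sub[column]))
        report["tests"][name] = asdict(cr)
    return report
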