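"""MATH scores: mutant-allele tumor heterogeneity from MAF distributions.

The MATH score summarizes intratumoral genetic heterogeneity as the ratio of
the width to the center of a sample's mutant-allele-frequency distribution:

    MATH = 100 * MAD / median(MAF)

where MAD is the median absolute deviation scaled by 1.4826 (the constant that
makes the MAD a consistent estimator of the standard deviation under
normality, and the default in R's ``mad``). Heterogeneous tumors — those with
several subclones at distinct cancer-cell fractions — have broader MAF
distributions and hence higher scores. Because tumor purity rescales all MAFs
jointly and the score is a ratio, MATH is first-order insensitive to normal
contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import SampleTable

#: Normal-consistency scale factor for the median absolute deviation,
#: as in R's mad() and the original MATH definition.
MAD_SCALE = 1.4826

#: Default minimum read depth for a variant's MAF to enter the distribution.
DEFAULT_MIN_DEPTH = 10

#: Default minimum number of qualifying variants for a defined score.
DEFAULT_MIN_VARIANTS = 5


@dataclass
class MATHResult:
    """Per-sample MAF dispersion summary.

    ``flag`` is empty for a valid score; otherwise it names why the score is
    unavailable ("too_few_variants" or "zero_median") and ``math_score`` is NaN.
    """

    sample_id: str
    n_variants: int
    median_maf: float
    mad: float
    math_score: float
    flag: str = ""

    @property
    def available(self) -> bool:
        return self.flag == ""


def extract_mafs(table: SampleTable, min_depth: int = DEFAULT_MIN_DEPTH) -> list[float]:
    """MAFs of all observations with total depth >= ``min_depth``, in input order."""
    if min_depth < 1:
        raise ValueError(f"min_depth must be >= 1, got {min_depth}")
    return [o.maf for o in table if o.depth >= min_depth]


def math_score(
    mafs, min_variants: int = DEFAULT_MIN_VARIANTS, sample_id: str = ""
) -> MATHResult:
    """MATH score of a MAF vector.

    Median is the standard sample median (midpoint of the central order
    statistics for even length); MAD is 1.4826 x median absolute deviation.
    Fewer than ``min_variants`` values, or a zero median, yields a flagged
    result rather than an exception.
    """
    mafs = np.asarray(list(mafs), dtype=float)
    n = mafs.size
    if n < min_variants:
        return MATHResult(sample_id, n, float("nan"), float("nan"), float("nan"), "too_few_variants")
    med = float(np.median(mafs))
    mad = MAD_SCALE * float(np.median(np.abs(mafs - med)))
    if med == 0.0:
        return MATHResult(sample_id, n, med, mad, float("nan"), "zero_median")
    return MATHResult(sample_id, n, med, mad, 100.0 * mad / med)


def sample_math(
    table: SampleTable,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_variants: int = DEFAULT_MIN_VARIANTS,
) -> MATHResult:
    """MATH score of one sample after the depth filter."""
    return math_score(extract_mafs(table, min_depth), min_variants, table.sample_id)


def cohort_math(
    tables,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_variants: int = DEFAULT_MIN_VARIANTS,
) -> pd.DataFrame:
    """Per-sample MATH table for a cohort.

    One row per sample (columns: sample_id, n_variants, median_maf, mad,
    math_score, flag); flagged samples are retained with NaN scores.
    """
    rows = [sample_math(t, min_depth, min_variants) for t in tables]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "n_variants": [r.n_variants for r in rows],
            "median_maf": [r.median_maf for r in rows],
            "mad": [r.mad for r in rows],
            "math_score": [r.math_score for r in rows],
            "flag": [r.flag for r in rows],
        }
    )


def summarize_cohort(math_table: pd.DataFrame) -> dict:
    """Summary statistics over the available (unflagged) scores of a cohort table."""
    scores = math_table.loc[math_table["flag"] == "", "math_score"].to_numpy(dtype=float)
    if scores.size == 0:
        return {"n_available": 0, "available": False}
    return {
        "n_available": int(scores.size),
        "available": True,
        "median": float(np.median(scores)),
        "mean": float(np.mean(scores)),
        "q1": float(np.percentile(scores, 25)),
        "q3": float(np.percentile(scores, 75)),
        "min": float(np.min(scores)),
        "max": float(np.max(scores)),
    }
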