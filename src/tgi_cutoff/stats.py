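"""Descriptive and inferential statistics for cohort tables.

Means ± SD per stratum with the omnibus test chosen by level count —
pooled-variance Student's t for two strata, one-way ANOVA with Tukey HSD
post-hoc for three or more — plus Geary's normality test.  Two-sided
p-values throughout; the conventional significance level is p < 0.05.

Geary's statistic is the ratio of mean absolute deviation to standard
deviation, ``a = mean|x - x̄| / sqrt(mean (x - x̄)^2)``, with null
expectation sqrt(2/π) ≈ 0.7979 under normality.  The z standardization
uses the classical first-order null scaling 0.2661/sqrt(n), an
approximation adequate for moderate-to-large n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CohortTable

__all__ = [
    "StrataSummary",
    "geary_test",
    "two_sample_t",
    "one_way_anova",
    "tukey_hsd",
    "stratified_summary",
]

GEARY_NULL = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class StrataSummary:
    """Per-stratum descriptive cell: n, mean ± SD."""

    stratum: str
    n: int
    mean: float
    sd: float


def geary_test(values) -> tuple[float, float, float]:
    """Geary's test of normality.

    Returns ``(a, z, p)`` where ``a`` is the mean-absolute-deviation to
    SD ratio (both moments with denominator n), ``z = (a - sqrt(2/π)) /
    (0.2661 / sqrt(n))`` and ``p`` is the two-sided normal p-value.
    Location/scale invariant.  Requires n >= 8 and non-zero variance.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 8:
        raise ValueError("Geary test needs n >= 8")
    dev = x - x.mean()
    rms = math.sqrt(float(np.mean(dev**2)))
    if rms == 0.0:
        raise ValueError("Geary test undefined for zero-variance data")
    a = float(np.mean(np.abs(dev))) / rms
    z = (a - GEARY_NULL) / (0.2661 / math.sqrt(len(x)))
    p = 2 * sps.norm.sf(abs(z))
    return a, float(z), float(p)


def two_sample_t(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance Student's t-test, two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        # degenerate pooled SD: identical constants are indistinguishable,
        # different constants are infinitely separated
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test, two-sided (optional alternative)."""
    res = sps.ttest_ind(np.asarray(group_a, float), np.asarray(group_b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F-test.

    Accepts k >= 2 groups (with k = 2 the F statistic is exactly the
    square of the pooled t); the stratified-summary dispatch reserves it
    for three or more strata.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrs):
        raise ValueError("each group needs n >= 2")
    res = sps.f_oneway(*arrs)
    return float(res.statistic), float(res.pvalue)


def tukey_hsd(groups, labels=None) -> pd.DataFrame:
    """Tukey honestly-significant-difference pairwise comparisons.

    Returns a frame with columns ``group_a, group_b, difference, p`` —
    one row per unordered pair, studentized-range based p-values.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 3 or any(len(g) < 2 for g in arrs):
        raise ValueError("Tukey HSD requires >= 3 groups of n >= 2")
    if labels is None:
        labels = [str(i) for i in range(len(arrs))]
    res = sps.tukey_hsd(*arrs)
    rows = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "difference": float(res.statistic[i, j]),
                    "p": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def stratified_summary(
    cohort: CohortTable | pd.DataFrame, value: str, strata: str
) -> tuple[list[StrataSummary], dict]:
    """Per-stratum n / mean / SD of ``value`` plus the omnibus test.

    Dispatches to the pooled t-test for exactly two strata and to one-way
    ANOVA with Tukey post-hoc for three or more, mirroring the
    conventional reporting rule.  Empty or all-missing strata are dropped
    and recorded in the audit.  Sample SDs (ddof=1).

    Returns ``(summaries, omnibus)`` where ``omnibus`` has keys
    ``test``, ``statistic``, ``p`` and, for ANOVA, ``tukey``.
    """
    df = cohort.data if isinstance(cohort, CohortTable) else cohort
    sub = df[[value, strata]].dropna(subset=[value])
    audit_dropped = int(len(df) - len(sub))
    levels = [lv for lv in sub[strata].dropna().unique()]
    levels.sort(key=str)
    groups, summaries = [], []
    for lv in levels:
        vals = sub.loc[sub[strata] == lv, value].to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        groups.append(vals)
        summaries.append(
            StrataSummary(
                stratum=str(lv),
                n=len(vals),
                mean=float(np.mean(vals)),
                sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            )
        )
    if len(groups) < 2:
        raise ValueError(f"strata column {strata!r} has fewer than 2 populated levels")
    omnibus: dict
    if len(groups) == 2:
        t, p = two_sample_t(groups[0], groups[1])
        omnibus = {"test": "student_t", "statistic": t, "p": p}
    else:
        f, p = one_way_anova(groups)
        omnibus = {
            "test": "anova",
            "statistic": f,
            "p": p,
            "tukey": tukey_hsd(groups, labels=[s.stratum for s in summaries]),
        }
    omnibus["n_missing_dropped"] = audit_dropped
    return summaries, omnibus
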