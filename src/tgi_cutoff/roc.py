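"""Empirical ROC analysis and optimal-cutoff selection.

Everything here is computed from scratch on the empirical distribution:

* :func:`empirical_roc` — one operating point per distinct observed score,
  under the convention *test positive iff score >= threshold*;
* :func:`auc_trapezoid` / :func:`auc_rank` — the same estimand by
  geometric and Mann–Whitney routes; both are evaluated in integer
  arithmetic on (TP, FP) counts so they agree exactly, ties counted half;
* :func:`delong_variance` / :func:`delong_test` — nonparametric AUC
  standard error and two-curve comparison from placement values
  (structural components);
* :func:`youden`, :func:`roc_distance`, :func:`likelihood_ratios` —
  per-threshold cutoff indices;
* :func:`select_optimal_cutoff` — threshold selection by maximum Youden J,
  minimum distance to the perfect-classification corner, or a combined
  ranking.

Sensitivity = TP / n_positive and specificity = TN / n_negative
throughout; all comparisons with thresholds are inclusive (``>=``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RocCurve",
    "CutoffIndices",
    "AucEstimate",
    "CutoffReport",
    "empirical_roc",
    "auc_trapezoid",
    "auc_rank",
    "delong_variance",
    "delong_test",
    "youden",
    "roc_distance",
    "likelihood_ratios",
    "select_optimal_cutoff",
    "cutoff_analysis",
]


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve.

    ``thresholds`` are strictly decreasing; ``tp[i]`` / ``fp[i]`` count
    positives / negatives with score >= ``thresholds[i]``.  The first point
    is the trivial (Se, Sp) = (0, 1) endpoint at threshold +inf; the last
    observed threshold is the minimum score, where (Se, Sp) = (1, 0).
    """

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    n_positive: int
    n_negative: int

    @property
    def sensitivity(self) -> np.ndarray:
        return self.tp / self.n_positive

    @property
    def specificity(self) -> np.ndarray:
        return (self.n_negative - self.fp) / self.n_negative

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class CutoffIndices:
    """Threshold-level diagnostic indices at one ROC operating point."""

    youden_j: float
    roc_distance: float
    lr_positive: float
    lr_negative: float


@dataclass(frozen=True)
class AucEstimate:
    """AUC with DeLong standard error and Wald 95% CI clipped to [0, 1]."""

    auc: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class CutoffReport:
    """A selected threshold with all its diagnostic indices."""

    threshold: float
    sensitivity: float
    specificity: float
    indices: CutoffIndices
    auc: AucEstimate | None = None
    policy: str = "combined"

    def to_dict(self) -> dict:
        d = {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden_j": self.indices.youden_j,
            "roc_distance": self.indices.roc_distance,
            "lr_positive": self.indices.lr_positive,
            "lr_negative": self.indices.lr_negative,
            "policy": self.policy,
        }
        if self.auc is not None:
            d.update(
                auc=self.auc.auc,
                auc_se=self.auc.se,
                auc_ci_low=self.auc.ci_low,
                auc_ci_high=self.auc.ci_high,
            )
        return d


def _split_classes(scores, states):
    scores = np.asarray(scores, dtype=float)
    states = np.asarray(states)
    if scores.shape != states.shape or scores.ndim != 1:
        raise ValueError("scores and states must be 1-d arrays of equal length")
    if states.dtype == bool:
        pos_mask = states
    else:
        uniq = set(np.unique(states).tolist())
        if uniq <= {0, 1}:
            pos_mask = states.astype(bool)
        elif uniq <= {"positive", "negative"}:
            pos_mask = states == "positive"
        else:
            raise ValueError(
                "states must be boolean, {0,1} or {'positive','negative'}; got %r" % sorted(uniq)
            )
    pos = scores[pos_mask]
    neg = scores[~pos_mask]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    return pos, neg


def empirical_roc(scores, states) -> RocCurve:
    """Build the empirical ROC curve of a score against a binary state.

    Parameters
    ----------
    scores : array-like
        Continuous test values (higher = more disease-like).
    states : array-like
        Binary truth per subject: booleans, {0, 1} or
        {"negative", "positive"}.

    Returns
    -------
    RocCurve
        One point per distinct observed score plus the (0, 1) endpoint.
    """
    pos, neg = _split_classes(scores, states)
    cuts = np.unique(np.concatenate([pos, neg]))[::-1]  # descending
    # counts of class members >= each threshold
    tp = len(pos) - np.searchsorted(np.sort(pos), cuts, side="left")
    fp = len(neg) - np.searchsorted(np.sort(neg), cuts, side="left")
    thresholds = np.concatenate([[np.inf], cuts])
    tp = np.concatenate([[0], tp])
    fp = np.concatenate([[0], fp])
    return RocCurve(
        thresholds=thresholds,
        tp=tp.astype(np.int64),
        fp=fp.astype(np.int64),
        n_positive=len(pos),
        n_negative=len(neg),
    )


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area under the empirical ROC curve.

    Evaluated as an integer sum over (TP, FP) count increments, divided
    once at the end, so it matches :func:`auc_rank` bit-for-bit.
    """
    tp, fp = curve.tp, curve.fp
    # twice the area in units of (n_pos * n_neg)
    twice = int(np.sum((fp[1:] - fp[:-1]) * (tp[1:] + tp[:-1])))
    return twice / (2 * curve.n_positive * curve.n_negative)


def auc_rank(scores, states) -> float:
    """Mann–Whitney AUC: P(X_pos > X_neg) + 0.5 * P(tie).

    The rank-statistic form of the same estimand as :func:`auc_trapezoid`;
    the two agree exactly because both reduce to the same integer count of
    concordant pairs (ties counted once, not half, in a doubled numerator).
    """
    pos, neg = _split_classes(scores, states)
    neg_sorted = np.sort(neg)
    gt = np.searchsorted(neg_sorted, pos, side="left")  # negatives strictly below
    ge = np.searchsorted(neg_sorted, pos, side="right")  # negatives <= pos
    twice = int(np.sum(gt + ge))  # 2*concordant + ties
    return twice / (2 * len(pos) * len(neg))


def _placements(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components.

    ``v10[i]`` is the fraction of negatives that positive i beats (ties
    half); ``v01[j]`` the fraction of positives that negative j is beaten
    by.  Computed by sorted-rank counting, O((m+n) log(m+n)).
    """
    ns = np.sort(neg)
    v10 = (np.searchsorted(ns, pos, side="left") + np.searchsorted(ns, pos, side="right")) / (
        2 * len(neg)
    )
    ps = np.sort(pos)
    v01 = (np.searchsorted(ps, neg, side="left") + np.searchsorted(ps, neg, side="right")) / (
        2 * len(pos)
    )
    return v10, v01


def delong_variance(scores, states) -> AucEstimate:
    """AUC with DeLong standard error and a Wald 95% CI.

    The variance estimator is ``var(V10)/m + var(V01)/n`` with sample
    variances (ddof=1) of the placement values.  Perfectly separated
    classes give se = 0.  Requires at least two subjects per class.
    """
    pos, neg = _split_classes(scores, states)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("DeLong variance needs >= 2 subjects per class")
    v10, v01 = _placements(pos, neg)
    auc = float(np.mean(v10))
    var = np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg)
    se = math.sqrt(max(var, 0.0))
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return AucEstimate(auc=auc, se=se, ci_low=lo, ci_high=hi)


def delong_test(group_a, group_b, paired: bool = False) -> tuple[float, float]:
    """DeLong comparison of two AUCs.

    Parameters
    ----------
    group_a, group_b : tuple of (scores, states)
        The two samples.  For disjoint strata (e.g. men vs women) use the
        default unpaired form, ``z = (A1 - A2) / sqrt(se1^2 + se2^2)``.
        With ``paired=True`` the two score vectors must come from the same
        subjects in the same order with identical states; the variance then
        subtracts twice the placement covariance.

    Returns
    -------
    (z, p) : two-sided normal test.
    """
    sa, ya = group_a
    sb, yb = group_b
    if not paired:
        ea = delong_variance(sa, ya)
        eb = delong_variance(sb, yb)
        num = ea.auc - eb.auc
        den = math.hypot(ea.se, eb.se)
    else:
        ya_arr = np.asarray(ya)
        yb_arr = np.asarray(yb)
        if len(sa) != len(sb) or not np.array_equal(ya_arr, yb_arr):
            raise ValueError("paired comparison requires the same subjects and states")
        pa, na = _split_classes(sa, ya)
        pb, nb = _split_classes(sb, yb)
        v10a, v01a = _placements(pa, na)
        v10b, v01b = _placements(pb, nb)
        num = float(np.mean(v10a) - np.mean(v10b))
        m, n = len(pa), len(na)
        s10 = np.cov(v10a, v10b, ddof=1)
        s01 = np.cov(v01a, v01b, ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / n
        den = math.sqrt(max(var, 0.0))
    if num == 0.0:
        return 0.0, 1.0
    if den == 0.0:
        return math.copysign(math.inf, num), 0.0
    z = num / den
    p = 2 * stats.norm.sf(abs(z))
    return z, float(p)


def _check_fraction(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


def youden(sensitivity: float, specificity: float) -> float:
    """Youden index J = Se + Sp - 1."""
    _check_fraction("sensitivity", sensitivity)
    _check_fraction("specificity", specificity)
    return sensitivity + specificity - 1.0


def roc_distance(sensitivity: float, specificity: float) -> float:
    """Euclidean distance from an ROC point to the perfect corner (Se=1, Sp=1)."""
    _check_fraction("sensitivity", sensitivity)
    _check_fraction("specificity", specificity)
    return math.hypot(1.0 - sensitivity, 1.0 - specificity)


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """Positive and negative likelihood ratios.

    LR+ = Se / (1 - Sp), LR- = (1 - Se) / Sp.  At the Sp = 1 (or Sp = 0)
    boundary the corresponding ratio is unbounded and reported as ``inf``.
    """
    _check_fraction("sensitivity", sensitivity)
    _check_fraction("specificity", specificity)
    lr_pos = sensitivity / (1.0 - specificity) if specificity < 1.0 else math.inf
    lr_neg = (1.0 - sensitivity) / specificity if specificity > 0.0 else math.inf
    return lr_pos, lr_neg


_POLICIES = ("max_youden", "min_distance", "combined")


def select_optimal_cutoff(
    curve: RocCurve, policy: str = "combined", auc: AucEstimate | None = None
) -> CutoffReport:
    """Select the optimal threshold on an empirical ROC curve.

    Policies
    --------
    ``max_youden``
        Maximize J = Se + Sp - 1.
    ``min_distance``
        Minimize the distance to the (Se, Sp) = (1, 1) corner.
    ``combined``
        Rank by J, break ties by smaller distance, then by larger LR+.

    All policies resolve remaining ties deterministically in favour of the
    higher threshold (more specific test).
    """
    if policy not in _POLICIES:
        raise ValueError(f"policy must be one of {_POLICIES}")
    se = curve.sensitivity
    sp = curve.specificity
    j = se + sp - 1.0
    dist = np.hypot(1.0 - se, 1.0 - sp)
    with np.errstate(divide="ignore"):
        lr_pos = np.where(sp < 1.0, se / np.where(sp < 1.0, 1.0 - sp, 1.0), np.inf)
    if policy == "min_distance":
        order = np.lexsort((-j, dist))
    else:  # max_youden and combined share the J-first ranking
        order = np.lexsort((-lr_pos, dist, -j))
    best = order[0]
    lrp, lrn = likelihood_ratios(float(se[best]), float(sp[best]))
    return CutoffReport(
        threshold=float(curve.thresholds[best]),
        sensitivity=float(se[best]),
        specificity=float(sp[best]),
        indices=CutoffIndices(
            youden_j=float(j[best]),
            roc_distance=float(dist[best]),
            lr_positive=lrp,
            lr_negative=lrn,
        ),
        auc=auc,
        policy=policy,
    )


def cutoff_analysis(scores, states, policy: str = "combined") -> CutoffReport:
    """Full single-sample analysis: ROC curve, DeLong AUC, optimal cutoff."""
    curve = empirical_roc(scores, states)
    auc = delong_variance(scores, states)
    return select_optimal_cutoff(curve, policy=policy, auc=auc)
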