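"""Reference-population selection.

To select a diagnostic cutoff for the TGI without circularity, subjects
are labelled healthy or unhealthy using only criteria that do NOT involve
triglycerides or glucose: abdominal obesity, total cholesterol, blood
pressure, and personal history of cardiometabolic disease (type 2
diabetes, coronary disease, arrhythmia, cerebrovascular disease,
polycystic ovaries, lipid-lowering medication).

Two steps:

1. :func:`apply_exclusions` — drop subjects with extreme triglycerides
   (>= 500 mg/dl by default) and, optionally, subjects without a baseline
   insulin value.
2. :func:`label_reference` — *healthy* subjects fail **no** criterion
   group; *unhealthy* subjects fail **all** enabled groups (configurable
   to "at least k"); everyone else belongs to neither group and is
   counted as *partial* in the audit.

The source population named only the criterion domains, not the
cholesterol or blood-pressure thresholds; the defaults here
(< 200 mg/dl total cholesterol, < 140/90 mmHg) are conventional clinical
values and every threshold is exposed in :class:`ReferenceCriteria`, so an
exact external reference set is not guaranteed reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .indices import classify_abdominal_obesity
from .io import CohortTable, FLAG_COLUMNS

__all__ = ["ReferenceCriteria", "ReferencePopulation", "apply_exclusions", "label_reference"]

DEFAULT_HISTORY = (
    "dm2", "coronary_disease", "arrhythmia",
    "cerebrovascular_disease", "pcos", "lipid_lowering_drugs",
)


@dataclass(frozen=True)
class ReferenceCriteria:
    """Thresholds and flags defining the healthy/unhealthy partition.

    ``tg_exclusion`` (mg/dl, exclusion is inclusive at the bound) is
    applied before any other rule.  ``unhealthy_min_failures`` configures
    the strictness of the unhealthy label: ``None`` (default) requires
    failing *all* enabled criterion groups; an integer k requires >= k.
    """

    tg_exclusion: float = 500.0
    require_insulin: bool = True
    cholesterol_max: float = 200.0
    sbp_max: float = 140.0
    dbp_max: float = 90.0
    use_abdominal_obesity: bool = True
    disqualifying_history: tuple[str, ...] = DEFAULT_HISTORY
    unhealthy_min_failures: int | None = None

    def __post_init__(self):
        for name in ("tg_exclusion", "cholesterol_max", "sbp_max", "dbp_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.disqualifying_history) - set(FLAG_COLUMNS)
        if unknown:
            raise ValueError(f"unknown history flags: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["disqualifying_history"] = list(self.disqualifying_history)
        return d


@dataclass
class ReferencePopulation:
    """Healthy/unhealthy partition with a per-rule audit trail."""

    healthy: CohortTable
    unhealthy: CohortTable
    audit: dict = field(default_factory=dict)

    @property
    def n_reference(self) -> int:
        return len(self.healthy) + len(self.unhealthy)

    def combined(self) -> pd.DataFrame:
        """Reference subjects with a ``reference_label`` column."""
        h = self.healthy.data.assign(reference_label="healthy")
        u = self.unhealthy.data.assign(reference_label="unhealthy")
        return pd.concat([h, u], ignore_index=True)

    def flow_report(self) -> str:
        """Human-readable selection flow mirroring the study diagram."""
        a = self.audit
        lines = [
            f"subjects in               {a.get('n_input', '?')}",
            f"  excluded TAG>=bound     {a.get('excluded_tg', 0)}",
            f"  excluded no insulin     {a.get('excluded_no_insulin', 0)}",
            f"eligible                  {a.get('n_eligible', '?')}",
            f"  healthy (fail none)     {len(self.healthy)}",
            f"  unhealthy (fail rule)   {len(self.unhealthy)}",
            f"  partial (neither)       {a.get('partial', 0)}",
            f"  unevaluable (missing)   {a.get('unevaluable', 0)}",
        ]
        return "\n".join(lines)


def apply_exclusions(cohort: CohortTable, criteria: ReferenceCriteria) -> CohortTable:
    """Apply the triglyceride and insulin-availability exclusions.

    Retains subjects with triglycerides strictly below
    ``criteria.tg_exclusion`` and, when ``require_insulin``, a non-missing
    insulin value.  Exclusion counts are recorded in provenance.
    """
    df = cohort.data
    tg_bad = df["triglycerides"] >= criteria.tg_exclusion
    ins_bad = df["insulin"].isna() if criteria.require_insulin else pd.Series(False, index=df.index)
    keep = ~(tg_bad | ins_bad)
    provenance = dict(cohort.provenance)
    provenance["exclusions"] = {
        "n_input": int(len(df)),
        "excluded_tg": int(tg_bad.sum()),
        "excluded_no_insulin": int((ins_bad & ~tg_bad).sum()),
        "n_retained": int(keep.sum()),
    }
    return CohortTable(data=df.loc[keep].reset_index(drop=True), provenance=provenance)


def _criterion_failures(df: pd.DataFrame, criteria: ReferenceCriteria):
    """Per-group failure indicators (pandas nullable booleans).

    Groups: abdominal obesity, total cholesterol, blood pressure (either
    systolic or diastolic at/above bound), disqualifying history (any
    flag true; missing flags make the group unknown unless another flag
    is already true).
    """
    groups = {}
    if criteria.use_abdominal_obesity:
        groups["abdominal_obesity"] = pd.array(
            classify_abdominal_obesity(df["waist"].to_numpy(), df["sex"].to_numpy()),
            dtype="boolean",
        )
    groups["cholesterol"] = pd.array(
        df["total_cholesterol"].to_numpy() >= criteria.cholesterol_max, dtype="boolean"
    )
    groups["blood_pressure"] = pd.array(
        (df["sbp"].to_numpy() >= criteria.sbp_max) | (df["dbp"].to_numpy() >= criteria.dbp_max),
        dtype="boolean",
    )
    if criteria.disqualifying_history:
        flags = df[list(criteria.disqualifying_history)]
        any_true = (flags == True).any(axis=1)  # noqa: E712
        any_missing = flags.isna().any(axis=1)
        hist = pd.array(any_true, dtype="boolean")
        hist[np.asarray(any_missing & ~any_true)] = pd.NA
        groups["history"] = hist
    return groups


def label_reference(cohort: CohortTable, criteria: ReferenceCriteria) -> ReferencePopulation:
    """Partition an exclusion-filtered cohort into healthy and unhealthy.

    Healthy subjects fail no criterion group; unhealthy subjects fail all
    enabled groups (or >= ``unhealthy_min_failures`` if set).  Subjects
    failing some but not enough groups, and subjects whose label cannot be
    decided because a needed field is missing, go to neither side and are
    audited as ``partial`` / ``unevaluable``.  Triglycerides and glucose
    are never inspected.
    """
    df = cohort.data
    groups = _criterion_failures(df, criteria)
    fail = pd.DataFrame({k: pd.Series(v, index=df.index) for k, v in groups.items()})
    n_groups = fail.shape[1]
    need = n_groups if criteria.unhealthy_min_failures is None else criteria.unhealthy_min_failures

    n_fail_min = (fail == True).sum(axis=1)  # noqa: E712  missing counted as not failing
    n_fail_max = n_fail_min + fail.isna().sum(axis=1)  # missing counted as failing
    healthy_mask = (n_fail_max == 0).to_numpy()
    unhealthy_mask = (n_fail_min >= need).to_numpy()
    unevaluable = (~healthy_mask & ~unhealthy_mask & fail.isna().any(axis=1)).to_numpy()
    partial = ~healthy_mask & ~unhealthy_mask & ~unevaluable

    audit = dict(cohort.provenance.get("exclusions", {}))
    audit["n_input"] = audit.get("n_input", int(len(df)))
    audit["n_eligible"] = int(len(df))
    audit["partial"] = int(partial.sum())
    audit["unevaluable"] = int(unevaluable.sum())
    audit["per_group_failures"] = {
        k: int((fail[k] == True).sum()) for k in fail.columns  # noqa: E712
    }

    base_prov = dict(cohort.provenance)
    healthy = CohortTable(
        data=df.loc[healthy_mask].reset_index(drop=True),
        provenance={**base_prov, "reference_label": "healthy"},
    )
    unhealthy = CohortTable(
        data=df.loc[unhealthy_mask].reset_index(drop=True),
        provenance={**base_prov, "reference_label": "unhealthy"},
    )
    return ReferencePopulation(healthy=healthy, unhealthy=unhealthy, audit=audit)
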