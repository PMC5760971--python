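"""Cohort table I/O and validation.

The interchange format is a UTF-8, comma-separated CSV with a dot decimal
point, one row per subject.  Columns (all required, in any order):

========================  =====================================================
column                    meaning / units
========================  =====================================================
subject_id                opaque unique string
sex                       ``female`` or ``male``
age                       years, integer >= 18
ethnicity                 mixed | white_hispanic | afro_venezuelan |
                          american_indian | other
waist                     waist circumference, cm
weight                    kg
height                    cm
sbp, dbp                  systolic / diastolic blood pressure, mmHg
glucose                   fasting glucose, mg/dl
triglycerides             fasting triglycerides, mg/dl
total_cholesterol         mg/dl
hdl                       mg/dl
insulin                   fasting insulin, µU/ml — may be missing (empty)
dm2, coronary_disease,    personal-history flags, {0, 1}, empty = missing
arrhythmia,
cerebrovascular_disease,
pcos, lipid_lowering_drugs
========================  =====================================================

Units are fixed: mg/dl for glucose and lipids, µU/ml for insulin.  No SI
auto-conversion is attempted — silently mixing mmol/l would corrupt the
TGI scale.  Missing values are empty fields; arithmetic on a missing value
downstream is an error, never silent NaN propagation.

Rows violating a validation rule are dropped and counted per reason in the
table's provenance, never silently ignored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortTable", "SchemaError", "read_cohort", "write_cohort", "validate_cohort",
           "NUMERIC_COLUMNS", "FLAG_COLUMNS", "ALL_COLUMNS"]

SEXES = ("female", "male")
ETHNICITIES = ("mixed", "white_hispanic", "afro_venezuelan", "american_indian", "other")

#: strictly-positive numeric columns (insulin alone may be missing)
NUMERIC_COLUMNS = (
    "age", "waist", "weight", "height", "sbp", "dbp",
    "glucose", "triglycerides", "total_cholesterol", "hdl", "insulin",
)
FLAG_COLUMNS = (
    "dm2", "coronary_disease", "arrhythmia",
    "cerebrovascular_disease", "pcos", "lipid_lowering_drugs",
)
ALL_COLUMNS = ("subject_id", "sex", "ethnicity") + NUMERIC_COLUMNS + FLAG_COLUMNS


class SchemaError(ValueError):
    """A mandatory column is absent or unusable."""


@dataclass
class CohortTable:
    """A validated cohort with provenance.

    ``data`` holds one row per subject with the columns documented in this
    module (history flags as pandas nullable booleans).  ``provenance``
    records the source, the row count read, and per-reason drop counts.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_dropped(self) -> int:
        return sum(self.provenance.get("dropped", {}).values())


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    for col in ("sex", "ethnicity"):
        df[col] = df[col].astype(str).str.strip().str.lower()
    for col in NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in FLAG_COLUMNS:
        raw = pd.to_numeric(df[col], errors="coerce")
        flags = pd.array([pd.NA] * len(df), dtype="boolean")
        flags[raw == 1] = True
        flags[raw == 0] = False
        df[col] = flags
    return df


def validate_cohort(df: pd.DataFrame, source: str = "<memory>") -> CohortTable:
    """Validate a raw cohort frame, dropping and counting bad rows.

    Rules (each failing row is dropped, first matching reason counted):
    non-numeric or non-positive lab/anthropometric value; missing any
    mandatory field (everything but insulin and the history flags);
    age < 18; unknown sex or ethnicity; pcos flagged in a male; duplicate
    subject_id (first occurrence kept).
    """
    missing_cols = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing_cols)}")
    df = _coerce_types(df[list(ALL_COLUMNS)])

    dropped: Counter = Counter()
    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, reason: str) -> None:
        new = mask.fillna(False).astype(bool) & ~bad
        if new.any():
            dropped[reason] += int(new.sum())
            bad[new] = True

    mandatory_numeric = [c for c in NUMERIC_COLUMNS if c != "insulin"]
    flag(df[mandatory_numeric].isna().any(axis=1), "missing_or_nonnumeric_value")
    for col in mandatory_numeric:
        flag(df[col] <= 0, "nonpositive_value")
    flag(df["insulin"] <= 0, "nonpositive_value")
    flag(df["age"] < 18, "age_below_18")
    flag(~df["sex"].isin(SEXES), "unknown_sex")
    flag(~df["ethnicity"].isin(ETHNICITIES), "unknown_ethnicity")
    flag((df["sex"] == "male") & (df["pcos"] == True), "pcos_in_male")  # noqa: E712
    flag(df["subject_id"].duplicated(keep="first"), "duplicate_subject_id")

    clean = df.loc[~bad].reset_index(drop=True)
    clean["age"] = clean["age"].astype(int)
    provenance = {"source": source, "n_read": int(len(df)), "dropped": dict(dropped)}
    return CohortTable(data=clean, provenance=provenance)


def read_cohort(path, schema: dict[str, str] | None = None) -> CohortTable:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    schema : dict, optional
        Mapping from the file's column names to the canonical names, for
        ingesting files with legacy headers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    if schema:
        df = df.rename(columns=schema)
    return validate_cohort(df, source=str(path))


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort back to canonical CSV.

    Booleans become {0, 1}; missing values become empty fields.  The
    output round-trips through :func:`read_cohort` with field-value
    equality.
    """
    df = cohort.data.copy()
    for col in FLAG_COLUMNS:
        df[col] = df[col].map({True: 1, False: 0}).astype("Int64")
    df[list(ALL_COLUMNS)].to_csv(path, index=False, na_rep="")
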