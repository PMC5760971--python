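"""Per-subject derived clinical indices.

The triglyceride-glucose index (TGI) is a surrogate marker of insulin
resistance computable from two routine fasting labs:

    TGI = ln(triglycerides [mg/dl] * glucose [mg/dl]) / 2

It is a natural-log-scale quantity; typical adult values fall between
roughly 4 and 5.5.  Insulin resistance itself is operationalized through a
HOMA score (homeostasis model assessment) with an inclusive threshold,
IR iff HOMA >= 2 by default.

All classification boundaries in this module are lower-bound inclusive
(``>=``).
"""

from __future__ import annotations

import warnings
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "compute_tgi",
    "compute_homa_ir",
    "classify_ir",
    "compute_bmi",
    "classify_bmi",
    "classify_abdominal_obesity",
    "classify_glycemic_status",
    "add_derived_indices",
    "IRStatus",
    "GlycemicStatus",
    "BMIClass",
    "HOMA_IR_THRESHOLD",
    "WAIST_CUTOFF_FEMALE",
    "WAIST_CUTOFF_MALE",
]

#: Inclusive HOMA threshold defining insulin resistance.
HOMA_IR_THRESHOLD = 2.0

#: Population-specific abdominal-obesity waist cutoffs (cm), inclusive.
WAIST_CUTOFF_FEMALE = 90.0
WAIST_CUTOFF_MALE = 95.0


class IRStatus(str, Enum):
    RESISTANT = "resistant"
    SENSITIVE = "sensitive"
    UNKNOWN = "unknown"


class GlycemicStatus(str, Enum):
    EUGLYCEMIC = "euglycemic"
    IMPAIRED_FASTING_GLUCOSE = "impaired_fasting_glucose"
    DM2 = "dm2"


class BMIClass(str, Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE_I = "obese_I"
    OBESE_II = "obese_II"
    OBESE_III = "obese_III"


def _require_positive(name: str, value) -> None:
    if np.any(np.asarray(value, dtype=float) <= 0):
        raise ValueError(f"{name} must be strictly positive")


def compute_tgi(triglycerides, glucose):
    """Triglyceride-glucose index: ``ln(TAG * FG) / 2``.

    Parameters
    ----------
    triglycerides : float or array-like
        Fasting triglycerides in mg/dl, strictly positive.
    glucose : float or array-like
        Fasting glucose in mg/dl, strictly positive.

    Returns
    -------
    float or ndarray
        Dimensionless index on the natural-log scale.  Symmetric in its
        two arguments and strictly increasing in each.
    """
    _require_positive("triglycerides", triglycerides)
    _require_positive("glucose", glucose)
    tag = np.asarray(triglycerides, dtype=float)
    fg = np.asarray(glucose, dtype=float)
    out = (np.log(tag) + np.log(fg)) / 2.0
    return float(out) if out.ndim == 0 else out


def compute_homa_ir(glucose, insulin, calibration: float = 1.0):
    """HOMA insulin-resistance score, ``glucose * insulin / 405``.

    The classical HOMA1 formula with fasting glucose in mg/dl and fasting
    insulin in µU/ml.  ``calibration`` is an optional multiplicative
    constant for users who wish to rescale toward computer-model (HOMA2)
    outputs; the downstream cutoff machinery only requires a score that is
    monotone in true insulin resistance.
    """
    _require_positive("glucose", glucose)
    _require_positive("insulin", insulin)
    g = np.asarray(glucose, dtype=float)
    i = np.asarray(insulin, dtype=float)
    out = calibration * g * i / 405.0
    return float(out) if out.ndim == 0 else out


def classify_ir(homa, threshold: float = HOMA_IR_THRESHOLD):
    """Insulin-resistance status from a HOMA score; resistant iff ``homa >= threshold``."""
    if np.any(np.asarray(homa, dtype=float) < 0):
        raise ValueError("homa must be non-negative")
    scalar = np.isscalar(homa)
    homa = np.atleast_1d(np.asarray(homa, dtype=float))
    out = np.where(homa >= threshold, IRStatus.RESISTANT.value, IRStatus.SENSITIVE.value)
    return out[0] if scalar else out


def compute_bmi(weight, height):
    """Body-mass index in kg/m² from weight (kg) and height (cm).

    Heights outside 100–230 cm trigger a plausibility warning (common
    data-entry error: metres instead of centimetres) but the value is
    still computed.
    """
    _require_positive("weight", weight)
    _require_positive("height", height)
    h = np.asarray(height, dtype=float)
    if np.any((h < 100) | (h > 230)):
        warnings.warn("height outside plausible range 100-230 cm", stacklevel=2)
    out = np.asarray(weight, dtype=float) / (h / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


# WHO bands, lower bound inclusive.
_BMI_EDGES = [18.5, 25.0, 30.0, 35.0, 40.0]
_BMI_CLASSES = [
    BMIClass.UNDERWEIGHT,
    BMIClass.NORMAL,
    BMIClass.OVERWEIGHT,
    BMIClass.OBESE_I,
    BMIClass.OBESE_II,
    BMIClass.OBESE_III,
]


def classify_bmi(bmi):
    """WHO BMI class; band edges 18.5/25/30/35/40, lower bound inclusive."""
    scalar = np.isscalar(bmi)
    b = np.atleast_1d(np.asarray(bmi, dtype=float))
    idx = np.searchsorted(_BMI_EDGES, b, side="right")
    out = np.array([_BMI_CLASSES[i].value for i in idx])
    return out[0] if scalar else out


def classify_abdominal_obesity(waist, sex):
    """Abdominal obesity: waist >= 90 cm (female) or >= 95 cm (male), inclusive."""
    _require_positive("waist", waist)
    scalar = np.isscalar(waist)
    w = np.atleast_1d(np.asarray(waist, dtype=float))
    s = np.atleast_1d(np.asarray(sex, dtype=object))
    cutoff = np.where(s == "male", WAIST_CUTOFF_MALE, WAIST_CUTOFF_FEMALE)
    out = w >= cutoff
    return bool(out[0]) if scalar else out


def classify_glycemic_status(glucose, dm2_history):
    """Fasting glycemic category (ADA-style bands).

    dm2 if known diabetes history or glucose >= 126 mg/dl; impaired
    fasting glucose for 100 <= glucose <= 125; euglycemic below 100.
    """
    _require_positive("glucose", glucose)
    scalar = np.isscalar(glucose)
    g = np.atleast_1d(np.asarray(glucose, dtype=float))
    hx = np.atleast_1d(np.asarray(dm2_history)).astype(bool)
    out = np.where(
        hx | (g >= 126.0),
        GlycemicStatus.DM2.value,
        np.where(g >= 100.0, GlycemicStatus.IMPAIRED_FASTING_GLUCOSE.value, GlycemicStatus.EUGLYCEMIC.value),
    )
    return out[0] if scalar else out


def add_derived_indices(df: pd.DataFrame, homa_threshold: float = HOMA_IR_THRESHOLD) -> pd.DataFrame:
    """Append all derived index columns to a validated cohort frame.

    Adds ``tgi``, ``homa_ir`` (NaN where insulin is missing), ``ir_status``
    (``unknown`` iff insulin missing), ``bmi``, ``bmi_class``,
    ``abdominal_obesity`` and ``glycemic_status``.  Missing insulin is the
    only tolerated missingness: HOMA arithmetic is never performed on it.
    """
    out = df.copy()
    out["tgi"] = compute_tgi(df["triglycerides"].to_numpy(), df["glucose"].to_numpy())
    homa = np.full(len(df), np.nan)
    status = np.full(len(df), IRStatus.UNKNOWN.value, dtype=object)
    have = df["insulin"].notna().to_numpy()
    if have.any():
        homa[have] = compute_homa_ir(
            df.loc[have, "glucose"].to_numpy(), df.loc[have, "insulin"].to_numpy()
        )
        status[have] = classify_ir(homa[have], threshold=homa_threshold)
    out["homa_ir"] = homa
    out["ir_status"] = status
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["bmi"] = compute_bmi(df["weight"].to_numpy(), df["height"].to_numpy())
    out["bmi_class"] = classify_bmi(out["bmi"].to_numpy())
    out["abdominal_obesity"] = classify_abdominal_obesity(
        df["waist"].to_numpy(), df["sex"].to_numpy()
    )
    out["glycemic_status"] = classify_glycemic_status(
        df["glucose"].to_numpy(), df["dm2"].fillna(False).to_numpy()
    )
    return out
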