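"""Synthetic cohort generation.

Emulates an adult cross-sectional metabolic cohort with the statistical
structure the cutoff analysis assumes, so every pipeline stage can be
exercised and validated without access to any real dataset:

* ~2000 subjects, 53.4% female; age bands <30 / 30–49 / >=50 with weights
  0.335 / 0.384 / 0.281;
* fasting triglycerides, glucose and insulin jointly lognormal, so the
  TGI — an average of two logs — is exactly Gaussian within each
  (sex × age-band) cell by construction;
* TGI cell means follow an additive structure (intercept + male shift
  0.10 + 0.17 per age band) calibrated to an overall mean ≈ 4.6 and SD
  ≈ 0.32;
* an insulin-resistance state (HOMA >= 2 by default) separable by TGI in
  the reference population with AUC ≈ 0.89;
* waist, blood pressure, cholesterol and history flags driven by a latent
  severity factor correlated with insulin, so the healthy / unhealthy
  reference labels are non-empty and metabolically coherent.

A ground-truth record (:class:`GeneratorTruth`) is returned alongside the
cohort for parameter-recovery tests.  Everything is reproducible from the
single ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CohortTable, ALL_COLUMNS, validate_cohort

__all__ = [
    "SyntheticSpec",
    "GeneratorTruth",
    "generate_cohort",
    "generate_binormal_scores",
    "binormal_auc",
    "binormal_youden_cutoff",
]

_ETHNICITY_LEVELS = ("mixed", "white_hispanic", "afro_venezuelan", "american_indian", "other")
_ETHNICITY_WEIGHTS = (0.765, 0.158, 0.029, 0.041, 0.007)
_AGE_BAND_RANGES = ((18, 29), (30, 49), (50, 79))


@dataclass(frozen=True)
class SyntheticSpec:
    """Distributional parameters of the synthetic cohort.

    The TGI mean of a (sex, band) cell is
    ``tgi_intercept + sex_tgi_shift * [male] + age_tgi_gradient * band``;
    the log-triglyceride mean is then back-solved from the (fixed)
    log-glucose mean, and the log-triglyceride SD from the within-cell
    TGI SD, the log-glucose SD and their correlation.
    """

    n: int = 2004
    female_fraction: float = 0.534
    age_band_weights: tuple[float, float, float] = (0.335, 0.384, 0.281)
    # TGI structure (natural-log-scale index units)
    tgi_intercept: float = 4.393
    sex_tgi_shift: float = 0.10
    age_tgi_gradient: float = 0.17
    tgi_within_sd: float = 0.29
    # lognormal labs
    log_glucose_mean: float = math.log(92.0)
    log_glucose_sd: float = 0.15
    log_insulin_mean: float = math.log(7.5)
    log_insulin_sd: float = 0.55
    # log-scale correlations: (triglycerides, glucose, insulin, severity)
    corr_tg_glucose: float = 0.3
    corr_tg_insulin: float = 0.82
    corr_glucose_insulin: float = 0.3
    corr_severity_tg: float = 0.40
    corr_severity_glucose: float = 0.15
    corr_severity_insulin: float = 0.55
    history_severity_slope: float = 1.4
    # insulin resistance
    ir_model: str = "homa_threshold"  # or "latent_class"
    homa_threshold: float = 2.0
    latent_class_intercept: float = -0.4
    latent_class_slope: float = 1.2
    # plumbing realism
    insulin_missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.age_band_weights) - 1.0) > 1e-9:
            raise ValueError("age_band_weights must sum to 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        for name in ("tgi_within_sd", "log_glucose_sd", "log_insulin_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ir_model not in ("homa_threshold", "latent_class"):
            raise ValueError("ir_model must be 'homa_threshold' or 'latent_class'")
        np.linalg.cholesky(self.correlation_matrix())  # PD check before sampling

    def log_tg_sd(self) -> float:
        """Log-triglyceride SD solving ``var(TGI) = (s_t^2 + s_g^2 + 2 r s_t s_g)/4``."""
        target = 4.0 * self.tgi_within_sd**2
        s_g, r = self.log_glucose_sd, self.corr_tg_glucose
        # s_t^2 + 2 r s_g s_t + (s_g^2 - target) = 0
        disc = (r * s_g) ** 2 - (s_g**2 - target)
        if disc <= 0:
            raise ValueError("tgi_within_sd too small for the configured glucose SD")
        return -r * s_g + math.sqrt(disc)

    def cell_tgi_mean(self, male: bool, band: int) -> float:
        return self.tgi_intercept + self.sex_tgi_shift * bool(male) + self.age_tgi_gradient * band

    def correlation_matrix(self) -> np.ndarray:
        """4x4 correlation of (log TG, log glucose, log insulin, severity)."""
        r = np.array(
            [
                [1.0, self.corr_tg_glucose, self.corr_tg_insulin, self.corr_severity_tg],
                [self.corr_tg_glucose, 1.0, self.corr_glucose_insulin, self.corr_severity_glucose],
                [self.corr_tg_insulin, self.corr_glucose_insulin, 1.0, self.corr_severity_insulin],
                [self.corr_severity_tg, self.corr_severity_glucose, self.corr_severity_insulin, 1.0],
            ]
        )
        return r

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_band_weights"] = list(self.age_band_weights)
        return d


@dataclass
class GeneratorTruth:
    """Pre-filtering ground truth for parameter-recovery tests."""

    spec: SyntheticSpec
    ir_state: np.ndarray  # boolean per subject, recorded before any filtering
    homa: np.ndarray  # true HOMA score (no missingness applied)
    tgi: np.ndarray
    severity: np.ndarray
    achieved: dict = field(default_factory=dict)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(spec: SyntheticSpec) -> tuple[CohortTable, GeneratorTruth]:
    """Draw a full synthetic cohort and its ground truth.

    All randomness flows from ``spec.seed`` through one generator stream
    with draws in fixed column order, so adding a downstream column never
    perturbs earlier ones.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    # demographics, in fixed order
    female = rng.random(n) < spec.female_fraction
    band = rng.choice(3, size=n, p=np.asarray(spec.age_band_weights))
    lo = np.array([_AGE_BAND_RANGES[b][0] for b in band])
    hi = np.array([_AGE_BAND_RANGES[b][1] for b in band])
    age = rng.integers(lo, hi + 1)
    ethnicity = rng.choice(
        len(_ETHNICITY_LEVELS), size=n, p=np.asarray(_ETHNICITY_WEIGHTS) / sum(_ETHNICITY_WEIGHTS)
    )

    # correlated log-scale labs + latent severity
    chol = np.linalg.cholesky(spec.correlation_matrix())
    z = rng.standard_normal((n, 4)) @ chol.T
    s_t = spec.log_tg_sd()
    tgi_cell = spec.tgi_intercept + spec.sex_tgi_shift * (~female) + spec.age_tgi_gradient * band
    log_tg = (2.0 * tgi_cell - spec.log_glucose_mean) + s_t * z[:, 0]
    log_g = spec.log_glucose_mean + spec.log_glucose_sd * z[:, 1]
    log_i = spec.log_insulin_mean + spec.log_insulin_sd * z[:, 2]
    severity = z[:, 3]

    triglycerides = np.exp(log_tg)
    glucose = np.exp(log_g)
    insulin = np.exp(log_i)
    tgi = (log_tg + log_g) / 2.0
    homa = glucose * insulin / 405.0

    # anthropometrics and blood pressure driven by severity + age
    height = np.where(female, 161.0, 172.0) + rng.normal(0, 7, n)
    bmi_latent = 26.0 + 2.2 * severity + rng.normal(0, 3.2, n)
    weight = np.clip(bmi_latent, 15, 60) * (height / 100.0) ** 2
    waist_base = np.where(female, 86.0, 92.0)
    waist = waist_base + 2.5 * band + 10.0 * severity + rng.normal(0, 7, n)
    waist = np.clip(waist, 55, None)
    sbp = 124.0 + 0.5 * (age - 40) + 13.0 * severity + rng.normal(0, 10, n)
    dbp = 78.0 + 0.2 * (age - 40) + 7.8 * severity + rng.normal(0, 8, n)
    sbp = np.clip(sbp, 80, None)
    dbp = np.clip(dbp, 45, None)
    total_chol = np.exp(math.log(188.0) + 0.05 * band + 0.14 * severity + rng.normal(0, 0.16, n))
    hdl = np.exp(math.log(45.0) - 0.05 * severity + rng.normal(0, 0.22, n))

    # history flags: logistic in severity and age
    agec = (age - 40) / 10.0
    sl = spec.history_severity_slope
    dm2 = rng.random(n) < _sigmoid(-3.3 + 0.55 * agec + sl * severity)
    cad = rng.random(n) < _sigmoid(-4.3 + 0.65 * agec + 0.8 * sl * severity)
    arr = rng.random(n) < _sigmoid(-4.6 + 0.45 * agec + 0.5 * sl * severity)
    cvd = rng.random(n) < _sigmoid(-5.2 + 0.70 * agec + 0.6 * sl * severity)
    pcos = female & (rng.random(n) < _sigmoid(-2.9 + 0.6 * sl * severity - 0.3 * agec))
    lld = rng.random(n) < _sigmoid(-3.6 + 0.6 * agec + sl * severity)

    # IR ground truth, recorded before any missingness or filtering
    if spec.ir_model == "homa_threshold":
        ir_state = homa >= spec.homa_threshold
    else:  # latent_class: decoupled from the generated insulin values
        ir_state = rng.random(n) < _sigmoid(
            spec.latent_class_intercept + spec.latent_class_slope * severity
        )

    insulin_out = insulin.copy()
    missing = rng.random(n) < spec.insulin_missing_rate
    insulin_out[missing] = np.nan

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "sex": np.where(female, "female", "male"),
            "ethnicity": np.asarray(_ETHNICITY_LEVELS, dtype=object)[ethnicity],
            "age": age,
            "waist": np.round(waist, 1),
            "weight": np.round(weight, 1),
            "height": np.round(height, 1),
            "sbp": np.round(sbp, 0),
            "dbp": np.round(dbp, 0),
            "glucose": np.round(glucose, 1),
            "triglycerides": np.round(triglycerides, 1),
            "total_cholesterol": np.round(total_chol, 1),
            "hdl": np.round(hdl, 1),
            "insulin": np.round(insulin_out, 2),
            "dm2": dm2.astype(int),
            "coronary_disease": cad.astype(int),
            "arrhythmia": arr.astype(int),
            "cerebrovascular_disease": cvd.astype(int),
            "pcos": pcos.astype(int),
            "lipid_lowering_drugs": lld.astype(int),
        },
        columns=list(ALL_COLUMNS),
    )
    cohort = validate_cohort(df, source=f"synthetic(seed={spec.seed})")

    truth = GeneratorTruth(
        spec=spec,
        ir_state=ir_state,
        homa=homa,
        tgi=tgi,
        severity=severity,
        achieved={
            "tgi_mean": float(np.mean(tgi)),
            "tgi_sd": float(np.std(tgi, ddof=1)),
            "ir_prevalence": float(np.mean(ir_state)),
            "insulin_missing": int(missing.sum()),
        },
    )
    return cohort, truth


def generate_binormal_scores(
    n_neg: int, n_pos: int, mu0: float, sd0: float, mu1: float, sd1: float, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Independent Gaussian scores per class; a ROC validation harness.

    Returns ``(scores, states)`` with negatives first; ``states`` is a
    boolean array marking positives.  ``seed`` may be an int or an
    existing :class:`numpy.random.Generator`.
    """
    if n_neg < 1 or n_pos < 1:
        raise ValueError("need at least one subject per class")
    if sd0 <= 0 or sd1 <= 0:
        raise ValueError("class SDs must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    neg = rng.normal(mu0, sd0, n_neg)
    pos = rng.normal(mu1, sd1, n_pos)
    scores = np.concatenate([neg, pos])
    states = np.concatenate([np.zeros(n_neg, bool), np.ones(n_pos, bool)])
    return scores, states


def binormal_auc(mu0: float, sd0: float, mu1: float, sd1: float) -> float:
    """Closed-form AUC of two Gaussian classes: Φ((μ1-μ0)/sqrt(σ0²+σ1²))."""
    if sd0 <= 0 or sd1 <= 0:
        raise ValueError("class SDs must be positive")
    return float(sps.norm.cdf((mu1 - mu0) / math.hypot(sd0, sd1)))


def binormal_youden_cutoff(mu0: float, sd0: float, mu1: float, sd1: float) -> float:
    """Closed-form Youden-optimal threshold for two Gaussian classes.

    J(t) = Φ((t-μ0)/σ0) - Φ((t-μ1)/σ1) is maximized where the two class
    densities cross; with equal SDs that is the midpoint of the means,
    otherwise the relevant root of the density-equality quadratic.
    """
    if sd0 <= 0 or sd1 <= 0:
        raise ValueError("class SDs must be positive")
    if math.isclose(sd0, sd1):
        return (mu0 + mu1) / 2.0
    a = 1.0 / sd0**2 - 1.0 / sd1**2
    b = -2.0 * (mu0 / sd0**2 - mu1 / sd1**2)
    c = mu0**2 / sd0**2 - mu1**2 / sd1**2 - 2.0 * math.log(sd1 / sd0)
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    j = sps.norm.cdf((roots - mu0) / sd0) - sps.norm.cdf((roots - mu1) / sd1)
    return float(roots[np.argmax(j)])
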