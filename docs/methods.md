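# Methods

## The index and the diagnostic question

The triglyceride-glucose index, `TGI = ln(TAG × FG)/2` with fasting
triglycerides (TAG) and fasting glucose (FG) both in mg/dl, is a
log-scale summary of two routine labs used as a surrogate for insulin
resistance (IR). The natural log and the division by 2 place typical
adult values near 4–5.5; doubling triglycerides raises the index by
exactly `ln(2)/2 ≈ 0.347`. The package treats IR as a binary state
derived from a HOMA score: `HOMA = FG × insulin / 405` (insulin in
µU/ml), resistant iff `HOMA ≥ 2`. This is the classical HOMA1 closed
form; computer-model (HOMA2) refinements have no published closed form,
so we expose an optional multiplicative calibration constant instead of
emulating them. The downstream cutoff machinery only requires an IR score
that is monotone in true resistance plus a threshold, so this choice
affects score values but not the structure of the analysis.

All classification bounds in the package are lower-bound inclusive
(`≥`): the IR rule, the WHO BMI bands (18.5/25/30/35/40), abdominal
obesity (waist ≥ 90 cm women, ≥ 95 cm men), fasting glycemic categories
(impaired fasting glucose at 100–125 mg/dl, diabetes at ≥ 126 or by
history), the triglyceride exclusion (≥ 500 mg/dl), and the test-positive
convention `score ≥ threshold`.

## Reference population

A cutoff for TGI must not be derived from criteria that themselves use
triglycerides or glucose. Subjects are therefore labelled using four
criterion groups — abdominal obesity, total cholesterol, blood pressure,
and personal history (type 2 diabetes, coronary disease, arrhythmia,
cerebrovascular disease, polycystic ovaries, lipid-lowering drugs) —
after excluding TAG ≥ 500 mg/dl and (by default) subjects without an
insulin value. *Healthy* subjects fail no group; *unhealthy* subjects
fail all enabled groups; everyone else is set aside and counted. The
"fail all" strictness is deliberately conservative and configurable
(`unhealthy_min_failures`) because the wording such designs use ("based
on all the following criteria") is genuinely ambiguous. The cholesterol
and blood-pressure thresholds of the original selection are not public;
the defaults (< 200 mg/dl, < 140/90 mmHg) are conventional clinical
values, and because they are choices, an externally reported reference
set is not guaranteed reproducible from the same cohort. A mutation test
verifies that perturbing a subject's triglycerides or glucose never
changes their label.

Within the reference population, the ROC state variable is the HOMA-based
`ir_status` (configurable). Labelling subjects healthy/unhealthy by
non-glycemic criteria and then scoring TGI against IR keeps the reference
sample metabolically polarized without making the cutoff circular.

## ROC machinery

The empirical ROC curve has one operating point per distinct observed
score plus the trivial (Se, Sp) = (0, 1) endpoint, with
`Se = TP/n_pos`, `Sp = TN/n_neg`. Two AUC estimators are provided and
must agree exactly: the trapezoid area over the curve and the
Mann–Whitney pair statistic (ties counted half). Both are evaluated as
integer pair counts divided once at the end, so the agreement is
bit-for-bit rather than to a tolerance; this identity is the package's
primary internal consistency check and is property-tested on tied data.

AUC uncertainty uses the DeLong structural-components estimator: the
placement value of each positive is the fraction of negatives it beats
(ties half), and symmetrically for negatives;
`var(AUC) = var(V10)/m + var(V01)/n` with sample variances. Placement
values are computed by sorted-rank counting in O((m+n) log(m+n)); an
O(m·n) double-loop oracle in the test suite checks the implementation to
machine precision. The 95% CI is Wald (`± 1.96 se`) clipped to [0, 1];
no logit transform is applied, keeping the interval directly comparable
to published normal-approximation intervals. Two-curve comparisons use
`z = (A₁ − A₂)/√(se₁² + se₂²)` for disjoint strata (sex, age bands) and
the placement-covariance form for paired same-subject comparisons.

Cutoff selection policies: `max_youden` (maximize `J = Se + Sp − 1`),
`min_distance` (minimize `√[(1−Se)² + (1−Sp)²]`, the distance to the
perfect corner — the distance formula is implemented as the *sum* of
squares, which the published index tables themselves satisfy), and
`combined` (rank by J, break ties by smaller distance, then larger LR+).
Since the exact multi-index tie-break used in published analyses is
rarely stated, `combined` documents its own ordering rather than claiming
fidelity to any one study. All remaining ties resolve to the higher
threshold (the more specific test). Selected thresholds are observed
score values, which makes selection equivariant under strictly monotone
score transforms. Cutoffs are reported to 2 decimals in human-readable
tables but applied at full precision.

## Cohort statistics

Stratified summaries report per-stratum n, mean, and sample SD, with the
omnibus test dispatched on the number of strata: pooled-variance
Student's t for two (Welch available but not the default, matching the
standard reporting convention when no unequal-variance caveat is made),
one-way ANOVA with Tukey HSD post-hoc for three or more. The t, F and
Tukey computations are delegated to scipy; Geary's normality test —
`a = mean|x − x̄| / √(mean(x − x̄)²)`, null expectation `√(2/π)`,
`z = (a − √(2/π))/(0.2661/√n)` — is implemented here because no
established Python library provides it. The 0.2661 null scaling is the
classical first-order approximation and is documented as approximate for
moderate n. Degenerate inputs are explicit errors or explicit limits:
zero-variance Geary is an error; a pooled t between two identical
constant groups is (0, 1) and between different constants (±∞, 0).

## Synthetic cohorts: what they emulate and what they don't

The generator emulates a cross-sectional adult metabolic-screening
cohort: n = 2004; 53.4% female; age bands <30 / 30–49 / ≥50 with weights
0.335 / 0.384 / 0.281; ethnicity labels at fixed frequencies with no
distributional effect (consistent with null ethnicity findings at this
scale). Triglycerides, glucose and insulin are jointly lognormal with
correlations (TG–glucose 0.3, glucose–insulin 0.3, TG–insulin 0.82) on
the log scale — triglycerides are right-skewed in real populations, and
lognormality makes the TGI exactly Gaussian within each (sex × age-band)
cell, matching the index's design. The TGI cell mean is
`4.393 + 0.10·[male] + 0.17·band`; the intercept is back-solved so the
population mean is ≈ 4.6, and the within-cell SD of 0.29 plus the
between-cell spread yields an overall SD ≈ 0.32, reproducing the
reported 4.6 ± 0.3 with its male–female and increasing-age gradients.
The TG–glucose correlation of 0.3 is a calibration choice (no published
covariance exists for it).

A latent "severity" factor correlated with log-insulin (0.55) and log-TG
(0.40) drives waist, blood pressure, total cholesterol and the history
flags, so criterion failures co-occur and both reference groups are
well-populated at study scale. Those loadings, together with the
TG–insulin correlation, were calibrated once so that the reference
population separates IR by TGI with AUC ≈ 0.89, the regime the method is
meant to operate in. The default IR state is mechanistic
(`HOMA ≥ 2` from the generated labs), so the HOMA-by-TGI-group contrast
emerges rather than being injected; a `latent_class` mode decouples the
IR state from the generated insulin for robustness testing. About 5% of
insulin values are blanked to exercise the missing-data path, and the
lognormal TG tail supplies a small number of ≥ 500 mg/dl exclusions.

What the generator does **not** emulate: assay noise and detection
limits, intra-subject day-to-day variability, survey design effects
(clustered multi-stage sampling, oversampling), medication effects on
lipids beyond a binary flag, and any non-lognormal tail behaviour.
Passing tests therefore demonstrate the correctness and calibration of
the *estimators* under a realistic correlation structure — not that any
particular clinical cutoff generalizes to a real population.

A separate binormal harness (two Gaussian classes) provides closed-form
oracles: `AUC = Φ((μ₁−μ₀)/√(σ₀²+σ₁²))` and the Youden-optimal threshold
from the density-crossing quadratic. These back the recovery tests: AUC
convergence to Φ(1) at n = 10,000 per class, DeLong CI coverage over 500
replicates, and mean Youden-cutoff recovery within ±0.10 index units on
reference samples of n = 350 (207 vs 143, the healthy/unhealthy scale)
over 100 replicates — problem sizes chosen to mirror the study-scale
sampling noise the method faces in practice.

## Numerical and design notes

- Exactness where it is free: AUC forms use integer arithmetic; ROC
  thresholds are observed scores, never interpolated.
- `LR+ = Se/(1−Sp)` at Sp = 1 (and `LR−` at Sp = 0) is reported as `inf`
  rather than an error; downstream ranking treats it as the strongest
  possible positive evidence.
- The single generator seed drives one stream with draws in fixed column
  order, so adding a downstream column cannot perturb earlier columns;
  correlation matrices are Cholesky-validated before any sampling.
- Validation drops rows, never imputes: each dropped row is counted under
  the first rule it violates, and validation is order-independent.
- The sex frequency ambiguity sometimes seen in published tables (a
  quoted female percentage differing slightly from its printed n/N) is
  left to the data: the column dictionary carries sex as recorded.

## Limitations

- HOMA1 is not HOMA2: absolute HOMA group means computed here are not
  directly comparable to computer-model values, though the IR partition
  at the same threshold is very similar.
- The DeLong Wald CI can slightly undercover for AUC near 1 or tiny
  class sizes; no bootstrap alternative is provided.
- The Geary z is a large-sample approximation; below n ≈ 50 its type-I
  error drifts from nominal.
- Cross-sectional only: no longitudinal layouts, no repeated measures,
  no survey weights.
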