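# tgi-cutoff

Optimal-cutoff analysis for the **triglyceride-glucose index (TGI)**, a
low-cost surrogate marker of insulin resistance:

```
TGI = ln( fasting triglycerides [mg/dl] × fasting glucose [mg/dl] ) / 2
```

Insulin resistance (IR) underlies type 2 diabetes, the metabolic syndrome
and cardiovascular risk, but its standard measures (euglycemic clamp,
insulin-based HOMA scores) need insulin assays that are impractical in
many clinical settings. The TGI needs only two routine fasting labs. This
package is for epidemiologists and clinical researchers who want to derive
and evaluate a population-specific TGI threshold for IR screening, and for
anyone who needs a careful, from-scratch implementation of the ROC cutoff
toolkit it rests on.

## What it does

- **Per-subject indices** — TGI; HOMA-IR (`glucose × insulin / 405`) with
  the inclusive IR rule HOMA ≥ 2; BMI with WHO classes; abdominal obesity
  (waist ≥ 90 cm women / ≥ 95 cm men); fasting glycemic categories.
- **Reference-population selection** — subjects are labelled healthy
  (fail no criterion) or unhealthy (fail all criterion groups) using only
  waist, cholesterol, blood pressure and disease history — never
  triglycerides or glucose, so the cutoff derivation is not circular.
  Extreme triglycerides (≥ 500 mg/dl) and missing insulin are excluded
  first; every threshold is configurable and every filter is audited.
- **ROC cutoff machinery (from scratch)** — empirical ROC curve with the
  inclusive `score ≥ threshold` convention; AUC by exactly-agreeing
  trapezoid and Mann–Whitney forms; DeLong placement-value standard
  errors, confidence intervals and two-curve tests (paired and unpaired);
  Youden index `J = Se + Sp − 1`, distance to the perfect ROC corner
  `√[(1−Se)² + (1−Sp)²]`, likelihood ratios `Se/(1−Sp)` and `(1−Se)/Sp`;
  threshold selection by max-Youden, min-distance, or a combined ranking.
  Exposed both as functions and as a scikit-learn estimator
  (`CutoffClassifier`) that composes with pipelines and grid search.
- **Cohort statistics** — stratified means ± SD with Student's t / one-way
  ANOVA + Tukey HSD dispatch, and Geary's normality test.
- **Synthetic cohorts** — a calibrated generator producing study-scale
  cohorts (~2000 adults, TGI ≈ 4.6 ± 0.3 with male and age gradients, a
  HOMA-based IR state separable by TGI with AUC ≈ 0.89) plus a binormal
  score harness with closed-form AUC and Youden-optimum oracles.

## Worked example

```python
from tgi_cutoff import AnalysisConfig, SyntheticSpec, run_analysis

config = AnalysisConfig(simulate=True, synthetic_spec=SyntheticSpec(seed=1), seed=1)
report = run_analysis(config)

total = report.cutoffs["total"]
print(f"selected cutoff : {total.threshold:.2f}")
print(f"sensitivity     : {100 * total.sensitivity:.1f}%")
print(f"specificity     : {100 * total.specificity:.1f}%")
print(f"Youden J        : {total.indices.youden_j:.2f}")
print(f"AUC (DeLong CI) : {total.auc.auc:.3f} "
      f"({total.auc.ci_low:.3f}-{total.auc.ci_high:.3f})")
hc = report.homa_contrast
print(f"HOMA above/below cutoff: {hc['mean_above']:.2f} vs {hc['mean_below']:.2f} "
      f"(p={hc['p']:.2g})")
```

prints

```
selected cutoff : 4.60
sensitivity     : 80.3%
specificity     : 76.4%
Youden J        : 0.57
AUC (DeLong CI) : 0.872 (0.846-0.898)
HOMA above/below cutoff: 2.66 vs 1.34 (p=3.7e-140)
```

The pipeline simulated a 2004-subject cohort, excluded extreme
triglycerides and missing insulin, partitioned the remainder into healthy
and unhealthy reference subjects, and selected the TGI threshold that best
separates insulin-resistant from insulin-sensitive reference subjects.
The cutoff of 4.60 classifies a subject as likely insulin resistant when
their TGI is at or above it; the AUC of 0.87 says a random IR subject
out-scores a random non-IR subject 87% of the time; and subjects at or
above the cutoff indeed carry much higher HOMA-IR levels (2.66 vs 1.34).

The same analysis runs from the shell:

```bash
tgi-cutoff run --simulate --seed 1 --out tgi_report        # full pipeline
tgi-cutoff simulate --n 2000 --seed 7 --out cohort.csv     # synthetic cohort CSV
tgi-cutoff roc --input scored.csv --score tgi --state ir   # one-score ROC analysis
```

and from real data via `tgi-cutoff run --input cohort.csv` with the CSV
schema documented in `tgi_cutoff.io`.

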