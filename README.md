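# readmit-audit

A reusable audit of **algorithmic bias in 30-day hospital readmission risk
models**, for health-services and biostatistics researchers who deploy (or
evaluate) standard readmission scores on linked administrative discharge
data and want to know whether the scores perform — and err — equally across
patient groups.

Real statewide discharge databases are licensed and cannot be
redistributed, so the package pairs the audit machinery with a **synthetic
discharge-data generator** that emulates their structure (patient linkage
keys, hospitals with varying Black-patient shares, race/income group labels,
clinical covariates, planned revisits, in-hospital deaths, AMA discharges,
broken linkage) under a *fully known* risk model, making every stage of the
audit testable against exact ground truth.

## What it computes

**Cohort.** Every admission is an index admission unless excluded (age < 18,
died in hospital, discharged against medical advice, missing linkage or
length of stay). A 30-day **unplanned readmission** is a subsequent linked
admission with `1 ≤ next.admit − index.discharge ≤ 30` that is not planned
(default: elective ⇒ planned; the predicate is pluggable).

**Risk models.**

| model | form | high-risk rule | cohort |
|---|---|---|---|
| LACE | points: LOS + acuity + Charlson + ED visits | score ≥ 10 | all eligible |
| modified HOSPITAL | points over 5 predictors (labs dropped) | score ≥ 5 | all eligible |
| CMS-style, as-is | logistic: age + condition indicators, supplied coefficients | Youden threshold | medicine cohort |
| CMS-style, retrained | same features refit on a random half (5-fold CV diagnostics) | Youden threshold | medicine test half |

**Performance per group** (all / race / income / payer): AUC (Mann-Whitney,
ties ½), Brier statistic (dichotomized by default, hence equal to the 0-1
loss; probability mode available), Hosmer-Lemeshow χ² over risk deciles,
observed vs model-predicted rates.

**Fairness** (equalized-odds error parity, protected − reference):

- ΔFNR = FNR_B − FNR_W (and low − other income), likewise ΔFPR and Δ0-1 loss,
  with two-tailed Welch t tests on the per-admission error indicators;
- between-group **generalized entropy index** over benefits
  b = ŷ − y + 1 ∈ {0, 1, 2}: GE(α) = 1/(n·α(α−1)) Σ[(bᵢ/μ)^α − 1] with each
  bᵢ replaced by its group mean (α = 2 by default).

**Hospital stratification**: within-hospital ΔFNR/ΔFPR (scatter data with
quadrant labels) and cumulative hospital-composition bins (pool admissions
of hospitals whose observed Black-patient share exceeds 0, 10 %, 20 %, …)
with 95 % Wald intervals on the pooled differences.

## Worked example

```python
from readmit_audit import AuditConfig, GeneratorConfig, run_audit

report = run_audit(AuditConfig(generator=GeneratorConfig(n_patients=20_000), seed=7))
print(report.metadata["n_eligible"])        # 31776 eligible index admissions
print(report.observed)                      # observed rates by group
print(report.bias.loc[0, ["diff_fnr", "diff_fpr"]])
```

With seed 7 this generates 34 757 admissions (2 981 excluded: 1 306 minors,
678 deaths, 304 AMA, 693 missing linkage). Observed unplanned 30-day
readmission rates are 13.7 % overall, 16.6 % for Black vs 12.6 % for White
patients and 15.6 % low-income vs 12.7 % other-income — the generator's
default conditions make the protected groups sicker on the score-visible
covariates. For LACE at the fixed pooled threshold of 10 points:

```
AUC 0.619, Brier (binary) 0.204
FNR  black 0.692  white 0.763   ΔFNR = −0.071  (p < 1e-5)
FPR  black 0.148  white 0.113   ΔFPR = +0.034  (p < 1e-9)
```

i.e. the *reference* group carries more false negatives and the *protected*
group more false positives — the signature of a pooled threshold applied to
groups with different risk distributions. The composition bins show the
same admissions pooled by hospital Black-patient share (`report.bins["lace"]`),
with 95 % CIs widening as the strata thin out.

A CLI wraps the same pipeline:

```bash
readmit-audit generate --outdir synth_out --seed 1   # records.csv + truth.csv
readmit-audit audit --outdir audit_out --seed 1      # full report bundle
readmit-audit report audit_out                       # summary metadata
```

Every run is deterministic: identical config + seed gives byte-identical
outputs (`report.json` carries the config hash).

## Layout

- `synthgen` — seeded SID-like hospital/discharge generator with ground truth
- `cohort` — exclusions, readmission labelling, observed rates
- `riskmodels` — LACE, modified HOSPITAL, CMS-style logistic, splits, Youden
- `performance` — AUC, Brier, Hosmer-Lemeshow, predicted rates
- `fairness` — confusion by group, error-rate differences, GEI, Welch tests
- `stratify` — per-hospital bias, composition bins, proportion-difference CIs
- `validation` — calibration/recovery/directional simulation studies
- `pipeline` / `cli` — one seeded, logged, reproducible run

See `docs/methods.md` for the model, parameter and design details, and the
limits of what the synthetic conditions can show.
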