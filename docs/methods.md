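# Methods

## The audit problem

A health system deploys a validated 30-day readmission risk score to target
transitional-care resources at high-risk patients. The audit question is
whether the score's errors are distributed evenly across patient groups:
under equalized-odds reasoning, a group with a higher false negative rate
(FNR) misses interventions it needed, and a group with a higher false
positive rate (FPR) absorbs resources without the measured need. This
package operationalizes that audit — cohort construction, scoring,
per-group performance, error-rate parity, inequality indices, and
hospital-level stratification — against administrative discharge data, and
ships a synthetic generator of such data with fully known risk structure so
the machinery itself can be validated end to end.

## Synthetic discharge data

### Structure

One row per inpatient admission. Patients carry a linkage key
(`patient_link_id`), race ∈ {white, black, other}, income ∈ {low, other},
sex and age; admissions carry timing in integer days from study start
(default timeline 1460 days), length of stay, admission type, Charlson
index, prior-6-month ED visits, prior-year admissions, oncology/procedure
flags, a 5-level specialty cohort label, and `n_condition_vars` (default
20) binary condition indicators standing in for the >100 condition
categories of hospital-wide readmission measures — kept at 20 by default so
desk-scale runs stay fast; configurable upward.

Hospitals (default 40) draw a target Black-patient share from
Beta(2, 8) (mean 0.2); a single float gives a degenerate composition.
Patients choose a hospital with weight proportional to that share (Black
patients) or its complement (others), so realized shares track targets and
create the composition gradient the stratified analyses need. All of a
patient's admissions occur at one hospital — a simplification; real
patients cross hospitals, which is precisely what statewide linkage keys
exist to capture.

### Outcome mechanism

Each admission independently "fires" an unplanned revisit with probability

    p = logistic(β₀ + β_age·(age−60)/10 + β_los·LOS + β_cci·CCI
                 + β_ed·ED + β_adm·PriorAdm + β_cond·conditions + δ_group)

and a fired revisit is materialized 1–30 days after discharge (emergent,
unplanned). Planned revisits (elective, flagged) are drawn **only among
admissions whose unplanned event did not fire** — making the two mutually
exclusive keeps each record's 30-day label exactly equal to its own fired
event, so the returned `true_event_prob` is an exact oracle for everything
downstream. Revisits can fire their own revisits (chains); successive
*index* episodes of a patient are laid ≥ 31 days apart so no accidental
within-window adjacency corrupts labels. Records beyond the study end are
dropped; affected index admissions are flagged `followup_complete = False`.
Repeat readmission events are independent across a patient's admissions — a
known simplification (no patient-level frailty term).

In-hospital deaths (2 %) terminate the patient's record stream, AMA
discharges (1 %), minors (4 % of patients) and broken linkage (2 % of
records) are injected at configurable rates to exercise the exclusion
logic.

### Group structure — the key design choice

Group differences in risk enter through **two** channels:

1. **Covariate shifts** (dominant): Black and low-income patients are
   younger but stay longer and carry more comorbidity, ED use, prior
   admissions and condition burden (shift sizes loosely calibrated to
   published all-payer discharge descriptives).
2. **Residual log-odds offsets** (small, default +0.05) for risk not
   captured by any covariate.

The distinction matters because the two channels push the fairness metrics
in *opposite* directions. A pure offset — same covariates, higher
prevalence — raises the protected group's FNR under a pooled threshold
(positives accrue relatively faster at low-score covariate values, by
log-concavity of the logistic). The empirically observed pattern in
readmission auditing — protected group with *higher FPR and lower FNR* —
arises when the protected group is sicker **on the covariates the score
sees**, shifting its score distribution upward. The defaults encode that
mechanism; under them the observed rates are ≈ 16 % (Black) vs ≈ 13 %
(White) and ≈ 15 % (low-income) vs ≈ 13 % (other), with point-score AUCs in
the low 0.6s — moderate discrimination, as deployed readmission scores
show.

`composition_attenuation ∈ [0, 1]` scales the race-based shifts and offset
by (1 − c·share) of the patient's hospital, so at c = 1 race differences
vanish as a hospital approaches 100 % Black patients — emulating settings
where majority-Black hospitals show similar outcomes for both groups.
Default 0 (no attenuation).

## Cohort and labelling

Exclusions are checked in a fixed priority order (missing linkage, missing
LOS, age < 18, died, AMA) so each excluded record carries one deterministic
primary reason; counts are conserved (excluded + eligible = all).

The readmission window is anchored at the index **discharge** day,
inclusive of day 30, with minimum gap 1 (same-day re-admission is treated
as a transfer/continuation). All three choices are configurable because
administrative definitions vary; enlarging the window can only add
positive labels (tested property). All linked records count as potential
revisits — including ones excluded as index admissions (a readmission
ending in death is still a readmission). Index admissions whose window
extends past the study end are retained but flagged, so users can filter;
observed rates default to the full eligible denominator.

## Risk models

- **LACE** (points): LOS bands 0/1/2/3/4–6/7–13/≥14 → 0/1/2/3/4/5/7;
  emergent +3; Charlson 0–3 as-is, ≥4 → 5; ED visits capped at 4.
  Threshold 10. The table ships as an editable dict so published variants
  can be substituted.
- **Modified HOSPITAL** (points): oncology 2, any procedure 1, nonelective
  1, prior-year admissions 0–1/2–5/>5 → 0/2/5, LOS ≥ 5 d → 2; the two
  laboratory items of the original score (hemoglobin, sodium) are absent
  from administrative data and are dropped, with the high-risk threshold at
  5 in the adjusted scoring. Maximum attainable score 11 (tested over the
  full predictor grid).
- **CMS-style logistic** over age (decades from 60) and the condition
  indicators; patient-level risk only (no hospital random effect), medicine
  cohort only. *As-is* uses supplied coefficients — in synthetic runs, the
  generator-truth coefficients perturbed by seeded N(0, 0.2) noise with a
  −0.3 intercept shift, emulating an externally derived measure that is
  locally miscalibrated (the scalar clinical effects its feature set cannot
  see are absorbed into the intercept at their population means; this
  stand-in is synthetic, no published coefficient set is bundled).
  *Retrained* refits by unpenalized logistic regression on a random half of
  the medicine cohort (5-fold stratified CV AUCs attached as diagnostics;
  final coefficients from the full retraining half — "5 cross-validations"
  is read as CV for diagnostics, not coefficient averaging) and is
  evaluated on the held-out half.
- **Thresholds**: point models use their fixed published operating points;
  classification is score ≥ threshold (strictness documented, config-
  urable). Logistic models use the Youden index: the observed score
  maximizing sensitivity + specificity − 1 under ≥ t, ties toward the
  larger threshold; for the retrained model the threshold is chosen on the
  retraining half to avoid test leakage.

## Measures

Per group: AUC (Mann-Whitney with ties ½), Brier statistic, Hosmer-
Lemeshow χ² with g = 10 quantile bins of predicted risk (ties share a bin;
bins with zero expected events merged with a neighbor; g − 2 degrees of
freedom), observed rate, and predicted rate (points models: share
classified high-risk; logistic models: mean predicted probability).

The **Brier default is binary mode** — the squared dichotomized call,
identical to the 0-1 loss — because that is the operational definition
under which point-score models are commonly reported; probability mode is
available for the logistic models. Which normalization a given published
audit used for point scores is often unstated, so both are provided rather
than guessed.

Fairness rows report per-group FNR/FPR/0-1 loss, protected-minus-reference
differences (fixed sign convention: Black − White, low − other), a
two-tailed Welch t test on per-admission error indicators (positives only
for FNR, negatives for FPR, everyone for 0-1 loss; Welch rather than
pooled-variance as the robust default; identical zero-variance samples give
p = 1), and the between-group generalized entropy index at α = 2 over
benefits b = ŷ − y + 1 restricted to the two contrasted groups. α and the
benefit definition are conventions of the fairness literature's reference
implementation, recorded in every output row; note the between-group index
is 0 whenever group *mean* benefits coincide, even if one group's errors
are all false negatives and the other's all false positives — a documented
insensitivity, which is why the signed FNR/FPR differences are the primary
measures. No multiple-testing correction is applied by default (a Holm
adjustment is available).

Stratification: per-hospital differences (hospitals missing a group or a
denominator are flagged and skipped), quadrant convention
I ⇔ (ΔFPR > 0, ΔFNR < 0). Composition bins are **cumulative** (> x %), with
the bin at 0 reproducing the global measures when every hospital serves
both groups; CIs are Wald intervals for a difference of proportions
(transparent, clamped to [−1, 1], degenerate proportions flagged; Newcombe
hybrid available). Bin composition is measured from observed analyzed
admissions, not generator targets.

## Validation studies (the `validation` module)

- **Type-I error**: Hosmer-Lemeshow at 5 % on *fitted* one-covariate
  logistic models (the setting in which the χ²(g−2) reference is valid —
  with known, unfitted probabilities the statistic is ≈ χ²(g) and g−2 df
  over-reject by construction); Welch t at 5 % with equal true rates;
  stratum CI coverage at 95 %. 1000 replicates each, n = 500–1000.
- **Parameter recovery**: a *designed, well-powered* estimation scenario —
  risk depends only on the model's features, condition prevalence raised to
  0.3 and base logit −2, intact linkage — under which the retrained model
  recovers every generator coefficient within 0.1 at ≈ 50 000 admissions.
  Under the default audit conditions (condition prevalence 0.08, outcome
  ≈ 12 %) the per-coefficient standard error is ≈ 0.08, so a 0.1 tolerance
  on the worst of 21 coefficients would be a coin flip on power grounds
  alone; recovery experiments are therefore run on the balanced design, as
  calibration studies should be.
- **Directional reproduction**: under the default conditions, LACE at its
  fixed pooled threshold shows ΔFPR > 0 and ΔFNR < 0 (protected vs
  reference) in ≥ 9 of 10 seeds at ≈ 50 000 admissions.
- **Composition shrink**: with full attenuation, amplified race shifts
  (×2.5) and a Beta(2, 4) composition spread — a scenario designed so upper
  bins are populated while retaining a reference-group minority — the
  binned |ΔFPR| declines toward 0 across thresholds (negative Spearman
  trend and smaller last-bin than first-bin value) in ≥ 8 of 10 seeds. The
  check uses the FPR difference deliberately: its denominators
  (non-readmitted patients) stay large in every stratum, whereas
  reference-group *positives* become so scarce in majority-Black strata
  that an FNR trend over 10 seeds is statistically unstable — the familiar
  wide-CI caveat of thin composition strata.

## Pipeline

One audit seed fans out to stage seeds by a fixed rule
(`SeedSequence([seed, k])`: k = 0 generation, 1 retraining split, 2 as-is
coefficient noise), so stages can be rerun in isolation. Reruns with the
same config are byte-identical (no timestamps in outputs; the config hash
excludes only the output directory). Point-score models are evaluated on
the full eligible cohort and the CMS-style models on the medicine cohort
(retrained: its test half); each report row carries its denominator. The
default problem sizes — 20 000 patients (~35 000 admissions) for examples,
~50 000–100 000 admissions for the simulation studies — keep any single
study under a minute on one CPU.

## What passing tests do and do not show

The generator reproduces the *structure* of linked discharge data and a
*chosen mechanism* of group difference; passing audits on it validate the
audit computations, not any claim about real populations. Real data differ
in ways the generator does not model: cross-hospital patient flow,
intra-patient outcome correlation, seasonal and secular trends, realistic
diagnosis coding (conditions here are exchangeable Bernoulli indicators),
payer-state interactions, race-income correlation, and under-documentation
of revisits that itself differs by group — the last being a central caveat
when interpreting real-world FNR/FPR gaps, since the observed outcome is
then a biased proxy for need. The between-group GEI magnitudes depend
strongly on the benefit scale and should be compared only within a run.
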