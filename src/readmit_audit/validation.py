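"""Simulation studies validating the audit machinery.

These are the package's own calibration checks: type-I error of the
Hosmer-Lemeshow test and of the group-difference t test under true nulls,
coverage of the stratum confidence interval, recovery of generator
coefficients by the retrained model, and directional reproduction of the
qualitative fairness patterns expected under the default synthetic
conditions (protected groups sicker on score-visible covariates, one pooled
threshold).  Each function is deterministic under its seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from . import riskmodels, synthgen
from .cohort import apply_exclusions, label_readmissions
from .fairness import bias_table, difference_test
from .performance import hosmer_lemeshow
from .stratify import composition_bins, per_hospital_bias, stratum_ci

__all__ = [
    "hl_null_rejection_rate",
    "ttest_null_rejection_rate",
    "stratum_ci_coverage",
    "cms_coefficient_recovery",
    "null_cv_auc",
    "lace_direction_by_seed",
    "composition_shrink_by_seed",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def hl_null_rejection_rate(n_reps: int = 1000, n: int = 1000, g: int = 10,
                           seed: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate of the Hosmer-Lemeshow test on correctly specified fits.

    Outcomes are drawn from a one-covariate logistic model and the
    probabilities re-fitted before testing — the classic setting in which
    the chi-square(g-2) reference applies.
    """
    rng = _rng(seed, 11)
    rejections = 0
    for _ in range(n_reps):
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-1.2 + 0.8 * x)).astype(int)
        if y.min() == y.max():
            continue
        fit = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500).fit(x[:, None], y)
        phat = fit.predict_proba(x[:, None])[:, 1]
        _, pval, _ = hosmer_lemeshow(phat, y, g=g)
        rejections += pval < alpha
    return rejections / n_reps


def ttest_null_rejection_rate(n_reps: int = 1000, n_per_group: int = 500,
                              p: float = 0.3, seed: int = 0,
                              alpha: float = 0.05) -> float:
    """Type-I error of the Welch t difference test with equal true rates."""
    rng = _rng(seed, 12)
    rejections = 0
    for _ in range(n_reps):
        a = (rng.random(n_per_group) < p).astype(int)
        b = (rng.random(n_per_group) < p).astype(int)
        rejections += difference_test(a, b) < alpha
    return rejections / n_reps


def stratum_ci_coverage(n_reps: int = 1000, n_per_group: int = 500,
                        p1: float = 0.3, p2: float = 0.2, seed: int = 0) -> float:
    """Empirical 95% coverage of the two-proportion difference interval."""
    rng = _rng(seed, 13)
    k1 = rng.binomial(n_per_group, p1, size=n_reps)
    k2 = rng.binomial(n_per_group, p2, size=n_reps)
    true = p1 - p2
    covered = 0
    for a, b in zip(k1, k2):
        _, lo, hi = stratum_ci(a / n_per_group, n_per_group, b / n_per_group, n_per_group)
        covered += lo <= true <= hi
    return covered / n_reps


def _recovery_config(seed: int, n_patients: int = 30_000,
                     age_effect: float = 0.3) -> synthgen.GeneratorConfig:
    """Correctly specified, well-powered estimation scenario.

    Risk depends only on the model's features (age + condition indicators)
    and linkage is intact, so observed labels equal the latent events.  The
    design is balanced for precision: condition indicators at prevalence 0.3
    and a common outcome (base logit -2), the standard way to set up a
    parameter-recovery experiment rather than a portrait of typical data.
    """
    return synthgen.GeneratorConfig(
        n_patients=n_patients,
        base_logit=-2.0,
        covariate_effects={"age_decade": age_effect, "los_days": 0.0, "charlson": 0.0,
                           "ed_visits_6mo": 0.0, "admissions_prior_year": 0.0},
        group_offsets={"black": 0.0, "low_income": 0.0},
        group_shifts={"black": synthgen.GroupShift(), "low_income": synthgen.GroupShift()},
        baseline=synthgen.CovariateBaseline(condition_prob=0.3),
        missing_link_prob=0.0,
        seed=seed,
    )


def _eligible_complete(config: synthgen.GeneratorConfig):
    hospitals = synthgen.generate_hospitals(config)
    records, truth = synthgen.generate_discharges(config, hospitals)
    labels = apply_exclusions(records)
    labels = label_readmissions(records, labels, study_end=config.study_days)
    merged = labels.merge(records, on="record_id", how="left", validate="1:1")
    return merged.loc[merged["eligible_index"] & merged["followup_complete"]].reset_index(
        drop=True)


def cms_coefficient_recovery(n_admissions: int = 50_000, seed: int = 0) -> dict:
    """Refit the CMS-style model on generated data with known coefficients.

    Returns the per-coefficient absolute errors (intercept, age, conditions)
    and the sample size actually used.
    """
    config = _recovery_config(seed, n_patients=int(n_admissions * 0.53))
    sub = _eligible_complete(config)
    spec = riskmodels.retrain_cms(sub, sub["readmit_30d_unplanned"],
                                  config.n_condition_vars, seed=seed)
    errors = {
        "intercept": abs(spec.intercept - config.base_logit),
        "age_decade": abs(spec.coefficients["age_decade"]
                          - config.covariate_effects["age_decade"]),
    }
    cond_err = np.abs(np.asarray(spec.coefficients["conditions"])
                      - config.condition_effects)
    errors["conditions_max"] = float(cond_err.max())
    errors["max_abs_error"] = float(max(errors["intercept"], errors["age_decade"],
                                        errors["conditions_max"]))
    errors["n"] = int(len(sub))
    errors["cv_auc"] = spec.cv_auc
    return errors


def null_cv_auc(n_admissions: int = 20_000, seed: int = 0) -> dict:
    """Cross-validated AUC when the outcome is independent of all covariates."""
    config = _recovery_config(seed, n_patients=int(n_admissions * 0.62), age_effect=0.0)
    config = dataclasses.replace(config, condition_effects=np.zeros(config.n_condition_vars))
    sub = _eligible_complete(config)
    spec = riskmodels.retrain_cms(sub, sub["readmit_30d_unplanned"],
                                  config.n_condition_vars, seed=seed)
    return {"mean_cv_auc": float(np.mean(spec.cv_auc)), "n": int(len(sub))}


def _default_run(seed: int, n_patients: int, **config_kw):
    config = synthgen.GeneratorConfig(n_patients=n_patients, seed=seed, **config_kw)
    sub = _eligible_complete(dataclasses.replace(config))
    scores = riskmodels.lace_score(sub)
    sub = sub.assign(score=scores, predicted_high_risk=scores >= 10)
    return config, sub


def lace_direction_by_seed(n_seeds: int = 10, n_patients: int = 27_000,
                           seed: int = 0) -> list[dict]:
    """Race-axis FNR/FPR differences of LACE under the default conditions.

    One pooled threshold with a sicker protected group should show the
    protected group with a higher FPR and lower FNR.
    """
    out = []
    for k in range(n_seeds):
        _, sub = _default_run(seed * 1000 + k, n_patients)
        row = bias_table(sub["predicted_high_risk"], sub["readmit_30d_unplanned"],
                         sub["race_group"].to_numpy(), "black", "white",
                         model_id="lace", axis="race")
        out.append({"seed": k, "diff_fnr": row["diff_fnr"], "diff_fpr": row["diff_fpr"],
                    "n": int(len(sub))})
    return out


def _shrink_scenario(seed: int, n_patients: int) -> synthgen.GeneratorConfig:
    """Composition-gradient scenario: race-based risk differences vanish as a
    hospital's Black share grows (full attenuation), with an amplified
    baseline bias and a composition spread wide enough to populate the upper
    bins while every bin keeps a reference-group minority."""
    shifts = dict(synthgen.default_group_shifts())
    b, amp = shifts["black"], 2.5
    shifts["black"] = synthgen.GroupShift(
        age_mean=b.age_mean, los_mean=amp * b.los_mean, charlson_mean=amp * b.charlson_mean,
        ed_mean=amp * b.ed_mean, prior_adm_mean=amp * b.prior_adm_mean,
        condition_prob=amp * b.condition_prob)
    return synthgen.GeneratorConfig(
        n_patients=n_patients, n_hospitals=25, hospital_composition=(2.0, 4.0),
        composition_attenuation=1.0, group_shifts=shifts,
        group_offsets={"black": 0.1, "low_income": 0.05}, seed=seed)


def composition_shrink_by_seed(n_seeds: int = 10, n_patients: int = 50_000,
                               seed: int = 0, measure: str = "diff_fpr") -> list[dict]:
    """Does the racial bias shrink across composition bins when the
    generator's race-based differences vanish in majority-Black hospitals?

    Shrinkage for one seed means the most-diverse nonempty bin has a smaller
    absolute difference than the all-hospitals bin, with a negative rank
    trend of |difference| against the bin threshold.  The default measure is
    the FPR difference: its denominators (non-readmitted patients) stay
    large in every stratum, whereas reference-group positives become too
    scarce in majority-Black strata for a stable FNR trend — the familiar
    small-stratum caveat of composition analyses.
    """
    from scipy.stats import spearmanr
    out = []
    for k in range(n_seeds):
        config = _shrink_scenario(seed * 1000 + k, n_patients)
        sub = _eligible_complete(config)
        scores = riskmodels.lace_score(sub)
        sub = sub.assign(score=scores, predicted_high_risk=scores >= 10)
        hb = per_hospital_bias(sub)
        bins = composition_bins(sub, hb)
        absd = bins[measure].abs().to_numpy()
        thr = bins["min_black_frac"].to_numpy()
        rho = spearmanr(thr, absd).statistic if len(bins) > 2 else np.nan
        out.append({
            "seed": k,
            "n_bins": int(len(bins)),
            "first_abs": float(absd[0]),
            "last_abs": float(absd[-1]),
            "trend_rho": float(rho),
            "shrinks": bool(len(bins) >= 3 and absd[-1] < absd[0] and rho < 0),
            "n": int(len(sub)),
        })
    return out
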