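"""Readmission risk models: LACE, modified HOSPITAL, and CMS-style logistic.

Four model variants are supported:

``lace``
    Point score summing Length of stay, Acuity (emergent admission),
    Charlson comorbidity and ED visits in the prior 6 months; fixed
    high-risk threshold of 10 points.
``hospital_mod``
    The HOSPITAL score with the two laboratory items (low hemoglobin, low
    sodium at discharge) removed, as administrative discharge data carry no
    labs; five retained predictors, fixed threshold of 5 points in the
    adjusted scoring.
``cms_asis``
    A CMS-style hospital-wide readmission measure: logistic model over age
    and condition-category indicators with externally supplied
    coefficients, patient-level risk only (no hospital effect), restricted
    to the medicine cohort; high-risk threshold from the Youden index.
``cms_retrained``
    The same feature set refit by logistic regression on a random half of
    the medicine cohort with 5-fold cross-validated AUC diagnostics;
    threshold from the Youden index.

Point tables ship as plain dicts (YAML-serializable) so any published
variant can be substituted.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "DEFAULT_LACE_TABLE",
    "DEFAULT_HOSPITAL_TABLE",
    "RiskModelSpec",
    "FittingError",
    "lace_score",
    "hospital_mod_score",
    "cms_features",
    "cms_linear_predictor",
    "split_retrain_test",
    "retrain_cms",
    "youden_threshold",
    "classify",
    "point_table_max",
]


class FittingError(RuntimeError):
    """Logistic retraining failed (separation / non-convergence)."""


# breakpoint tables: list of (upper_bound_inclusive, points); the last entry
# uses None as a catch-all upper bound.
DEFAULT_LACE_TABLE = {
    "los_days": [(0, 0), (1, 1), (2, 2), (3, 3), (6, 4), (13, 5), (None, 7)],
    "emergent": 3,
    "charlson": [(0, 0), (1, 1), (2, 2), (3, 3), (None, 5)],
    "ed_visits_6mo": [(0, 0), (1, 1), (2, 2), (3, 3), (None, 4)],
}

DEFAULT_HOSPITAL_TABLE = {
    "oncology_discharge": 2,
    "any_procedure": 1,
    "nonelective": 1,
    "admissions_prior_year": [(1, 0), (5, 2), (None, 5)],
    "los_ge_5": 2,
}


@dataclass
class RiskModelSpec:
    model_id: str                      # lace | hospital_mod | cms_asis | cms_retrained
    kind: str                          # points | logistic
    point_table: dict | None = None
    intercept: float = 0.0
    coefficients: dict | None = None   # {"age_decade": b, "conditions": [b_1..b_k]}
    threshold: float | None = None
    threshold_rule: str = "fixed"      # fixed | youden
    cohort_restriction: str = "none"   # none | medicine
    cv_auc: list = field(default_factory=list)  # retraining diagnostics

    def __post_init__(self):
        if self.kind not in ("points", "logistic"):
            raise ValueError(f"kind must be 'points' or 'logistic', got {self.kind!r}")
        if self.kind == "points" and self.point_table is None:
            raise ValueError("points model requires a point_table")
        if self.kind == "logistic" and self.coefficients is None:
            raise ValueError("logistic model requires coefficients")
        if self.threshold_rule == "fixed" and self.threshold is None:
            raise ValueError("fixed threshold rule requires a numeric threshold")


def _band_points(values: np.ndarray, bands) -> np.ndarray:
    """Map integer covariate values onto banded points."""
    pts = np.full(len(values), bands[-1][1], dtype=int)
    assigned = np.zeros(len(values), dtype=bool)
    for upper, p in bands:
        if upper is None:
            continue
        hit = ~assigned & (values <= upper)
        pts[hit] = p
        assigned |= hit
    return pts


def _require_nonnegative(records: pd.DataFrame, cols) -> None:
    for c in cols:
        if (records[c].to_numpy() < 0).any():
            raise ValueError(f"negative values in covariate {c!r}")


def lace_score(records: pd.DataFrame, table: dict | None = None) -> pd.Series:
    """LACE point score (L + A + C + E) per admission."""
    t = table or DEFAULT_LACE_TABLE
    _require_nonnegative(records, ("los_days", "charlson", "ed_visits_6mo"))
    score = (_band_points(records["los_days"].to_numpy(), t["los_days"])
             + np.where(records["admission_type"].to_numpy() == "emergent", t["emergent"], 0)
             + _band_points(records["charlson"].to_numpy(), t["charlson"])
             + _band_points(records["ed_visits_6mo"].to_numpy(), t["ed_visits_6mo"]))
    return pd.Series(score, index=records.index, name="lace")


def hospital_mod_score(records: pd.DataFrame, table: dict | None = None) -> pd.Series:
    """Modified HOSPITAL point score over the 5 retained predictors."""
    t = table or DEFAULT_HOSPITAL_TABLE
    _require_nonnegative(records, ("admissions_prior_year", "los_days"))
    score = (np.where(records["oncology_discharge"].to_numpy().astype(bool),
                      t["oncology_discharge"], 0)
             + np.where(records["any_procedure"].to_numpy().astype(bool),
                        t["any_procedure"], 0)
             + np.where(records["admission_type"].to_numpy() != "elective",
                        t["nonelective"], 0)
             + _band_points(records["admissions_prior_year"].to_numpy(),
                            t["admissions_prior_year"])
             + np.where(records["los_days"].to_numpy() >= 5, t["los_ge_5"], 0))
    return pd.Series(score, index=records.index, name="hospital_mod")


def point_table_max(table: dict) -> int:
    """Maximum attainable score for a point table."""
    total = 0
    for v in table.values():
        if isinstance(v, (int, float)):
            total += v
        else:
            total += max(p for _, p in v)
    return int(total)


# ---------------------------------------------------------------------------
# CMS-style logistic model


def cms_features(records: pd.DataFrame, n_condition_vars: int) -> pd.DataFrame:
    """Design matrix for the CMS-style model: age (decades from 60) + conditions."""
    cols = [f"cond_{j:02d}" for j in range(n_condition_vars)]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"records lack condition columns: {missing[:3]}...")
    X = pd.DataFrame(index=records.index)
    X["age_decade"] = (records["age_years"] - 60.0) / 10.0
    for c in cols:
        X[c] = records[c].astype(float)
    return X


def cms_linear_predictor(records: pd.DataFrame, spec: RiskModelSpec) -> pd.Series:
    """Predicted event probability logistic(intercept + b_age*age + b.cond)."""
    if spec.kind != "logistic":
        raise ValueError("cms_linear_predictor requires a logistic-kind spec")
    cond_coefs = np.asarray(spec.coefficients["conditions"], dtype=float)
    X = cms_features(records, len(cond_coefs))
    lp = (spec.intercept
          + spec.coefficients.get("age_decade", 0.0) * X["age_decade"].to_numpy()
          + X.iloc[:, 1:].to_numpy() @ cond_coefs)
    from scipy.special import expit
    return pd.Series(expit(lp), index=records.index, name=spec.model_id)


def split_retrain_test(records: pd.DataFrame, fraction: float = 0.5,
                       seed: int = 0) -> pd.Series:
    """Random record-level partition into 'train' / 'test'.

    Deterministic under the seed; with odd n the train half gets the extra
    record (train size = ceil(n * fraction)).
    """
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.ceil(n * fraction))
    part = np.empty(n, dtype=object)
    part[perm[:n_train]] = "train"
    part[perm[n_train:]] = "test"
    return pd.Series(part, index=records.index, name="partition")


def retrain_cms(train_records: pd.DataFrame, train_outcomes: pd.Series,
                n_condition_vars: int, folds: int = 5,
                seed: int = 0) -> RiskModelSpec:
    """Refit the CMS-style logistic model on the retraining half.

    Unpenalized logistic regression of the unplanned-readmission outcome on
    age and condition indicators.  ``folds``-fold stratified CV AUCs are
    attached as diagnostics; the returned coefficients come from a final fit
    on the full retraining set.  The returned spec uses the Youden threshold
    rule (threshold left unresolved until scores are available).
    """
    y = np.asarray(train_outcomes, dtype=int)
    if len(y) == 0 or y.min() == y.max():
        raise FittingError("retraining set must contain both outcome classes")
    X = cms_features(train_records, n_condition_vars).to_numpy()

    def _fit(Xa, ya):
        m = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        m.fit(Xa, ya)
        if not np.all(np.isfinite(m.coef_)):
            raise FittingError("non-finite coefficients; possible separation")
        return m

    cv_auc = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    for tr, va in skf.split(X, y):
        m = _fit(X[tr], y[tr])
        cv_auc.append(float(roc_auc_score(y[va], m.predict_proba(X[va])[:, 1])))

    final = _fit(X, y)
    coefs = final.coef_[0]
    return RiskModelSpec(
        model_id="cms_retrained", kind="logistic",
        intercept=float(final.intercept_[0]),
        coefficients={"age_decade": float(coefs[0]),
                      "conditions": [float(c) for c in coefs[1:]]},
        threshold=None, threshold_rule="youden", cohort_restriction="medicine",
        cv_auc=cv_auc,
    )


# ---------------------------------------------------------------------------
# thresholds and classification


def youden_threshold(scores, labels) -> float:
    """Observed score maximizing sensitivity + specificity - 1 under >=t.

    Ties in the Youden statistic break toward the larger threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = int(y.sum())
    neg = len(y) - pos
    if pos == 0 or neg == 0:
        raise ValueError("youden_threshold requires both outcome classes")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    tp = np.cumsum(y[order])
    fp = np.cumsum(1 - y[order])
    # candidates: last index of each distinct score (all records >= that score)
    last = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    j = tp[last] / pos - fp[last] / neg
    best = int(np.argmax(j))  # first occurrence = largest threshold on ties
    return float(s_sorted[last[best]])


def classify(scores, spec_or_threshold, model_id: str | None = None) -> pd.DataFrame:
    """Prediction table: record scores and the >= threshold high-risk flag."""
    if isinstance(spec_or_threshold, RiskModelSpec):
        spec = spec_or_threshold
        if spec.threshold is None:
            raise ValueError("threshold unresolved; compute it (e.g. Youden) first")
        threshold = spec.threshold
        model_id = model_id or spec.model_id
    else:
        threshold = float(spec_or_threshold)
        model_id = model_id or "model"
    s = pd.Series(scores)
    return pd.DataFrame({
        "score": s.to_numpy(),
        "predicted_high_risk": (s.to_numpy() >= threshold),
        "model_id": model_id,
        "threshold": threshold,
    }, index=s.index)


def make_asis_spec_from_truth(config, noise_scale: float = 0.2,
                              intercept_shift: float = -0.3,
                              seed: int = 0) -> RiskModelSpec:
    """CMS as-is stand-in for synthetic runs: generator-truth age/condition
    coefficients perturbed by seeded Gaussian noise, emulating a measure
    derived on an external population (synthetic; no published coefficient
    set is bundled)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    cond = np.asarray(config.condition_effects, dtype=float).copy()
    cond += rng.normal(0.0, noise_scale, size=cond.shape)
    age = config.covariate_effects.get("age_decade", 0.0) + rng.normal(0.0, noise_scale)
    # scalar clinical effects the feature set cannot see are absorbed into the
    # intercept at their population mean; the shift emulates local miscalibration
    absorbed = (config.covariate_effects.get("los_days", 0.0) * config.baseline.los_mean
                + config.covariate_effects.get("charlson", 0.0) * config.baseline.charlson_mean
                + config.covariate_effects.get("ed_visits_6mo", 0.0) * config.baseline.ed_mean
                + config.covariate_effects.get("admissions_prior_year", 0.0)
                * config.baseline.prior_adm_mean)
    return RiskModelSpec(
        model_id="cms_asis", kind="logistic",
        intercept=float(config.base_logit + absorbed + intercept_shift),
        coefficients={"age_decade": float(age), "conditions": [float(c) for c in cond]},
        threshold=None, threshold_rule="youden", cohort_restriction="medicine",
    )


def copy_spec(spec: RiskModelSpec) -> RiskModelSpec:
    return copy.deepcopy(spec)
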