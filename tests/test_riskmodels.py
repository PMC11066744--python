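"""Point scores, CMS-style logistic model, splits and thresholds."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from readmit_audit import riskmodels as rm
from conftest import make_records


# independent scalar re-implementations used as table-lookup oracles
def _lace_oracle(los, emergent, charlson, ed):
    if los <= 0:
        l = 0
    elif los <= 3:
        l = los
    elif los <= 6:
        l = 4
    elif los <= 13:
        l = 5
    else:
        l = 7
    c = charlson if charlson <= 3 else 5
    e = min(ed, 4)
    return l + (3 if emergent else 0) + c + e


def _hospital_oracle(onc, proc, nonelective, prior, los):
    p = 0 if prior <= 1 else (2 if prior <= 5 else 5)
    return 2 * onc + proc + nonelective + p + (2 if los >= 5 else 0)


def test_lace_worked_example():
    rec = make_records([{"los_days": 5, "admission_type": "emergent",
                         "charlson": 2, "ed_visits_6mo": 1}])
    score = rm.lace_score(rec)
    assert score.iloc[0] == 10  # 4 + 3 + 2 + 1
    assert rm.classify(score, 10).loc[0, "predicted_high_risk"]


def test_lace_minimal_not_high_risk():
    rec = make_records([{"los_days": 1, "admission_type": "elective",
                         "charlson": 0, "ed_visits_6mo": 0}])
    score = rm.lace_score(rec)
    assert score.iloc[0] == 1
    assert not rm.classify(score, 10).loc[0, "predicted_high_risk"]


def test_lace_matches_lookup_oracle():
    rng = np.random.default_rng(5)
    rows = [{"los_days": int(rng.integers(0, 25)),
             "admission_type": "emergent" if rng.random() < 0.7 else "elective",
             "charlson": int(rng.integers(0, 8)),
             "ed_visits_6mo": int(rng.integers(0, 7))} for _ in range(50)]
    rec = make_records(rows)
    got = rm.lace_score(rec)
    for i, row in enumerate(rows):
        exp = _lace_oracle(row["los_days"], row["admission_type"] == "emergent",
                           row["charlson"], row["ed_visits_6mo"])
        assert got.iloc[i] == exp


def test_hospital_worked_example():
    rec = make_records([{"oncology_discharge": 1, "admission_type": "emergent",
                         "los_days": 6, "any_procedure": 0, "admissions_prior_year": 0}])
    score = rm.hospital_mod_score(rec)
    assert score.iloc[0] == 5  # oncology 2 + nonelective 1 + LOS>=5 2
    assert rm.classify(score, 5).loc[0, "predicted_high_risk"]


def test_hospital_zero_case():
    rec = make_records([{"oncology_discharge": 0, "any_procedure": 0,
                         "admission_type": "elective", "admissions_prior_year": 0,
                         "los_days": 2}])
    assert rm.hospital_mod_score(rec).iloc[0] == 0


def test_hospital_bounded_by_table_max_on_full_grid():
    cap = rm.point_table_max(rm.DEFAULT_HOSPITAL_TABLE)
    assert cap == 11
    rows = [{"oncology_discharge": o, "any_procedure": pr,
             "admission_type": "elective" if el else "emergent",
             "admissions_prior_year": prior, "los_days": los}
            for o, pr, el, prior, los in itertools.product(
                (0, 1), (0, 1), (0, 1), (0, 1, 2, 5, 6, 9), (0, 4, 5, 20))]
    scores = rm.hospital_mod_score(make_records(rows))
    assert scores.between(0, cap).all()
    for i, row in enumerate(rows):
        exp = _hospital_oracle(row["oncology_discharge"], row["any_procedure"],
                               row["admission_type"] != "elective",
                               row["admissions_prior_year"], row["los_days"])
        assert scores.iloc[i] == exp


def test_negative_covariate_rejected():
    rec = make_records([{"charlson": -1}])
    with pytest.raises(ValueError, match="negative"):
        rm.lace_score(rec)


def _logistic_spec(intercept, age=0.0, conds=None, k=20):
    conds = [0.0] * k if conds is None else conds
    return rm.RiskModelSpec(model_id="cms_asis", kind="logistic", intercept=intercept,
                            coefficients={"age_decade": age, "conditions": conds},
                            threshold=0.5)


def test_cms_linear_predictor_closed_forms():
    rec = make_records([{"age_years": 60.0}])
    for j in range(20):
        rec[f"cond_{j:02d}"] = 0
    assert rm.cms_linear_predictor(rec, _logistic_spec(0.0)).iloc[0] == pytest.approx(0.5)
    assert rm.cms_linear_predictor(rec, _logistic_spec(-2.0)).iloc[0] == pytest.approx(
        expit(-2.0), abs=1e-6)
    rec["cond_03"] = 1
    spec = _logistic_spec(-1.0, age=0.2, conds=[0.0] * 3 + [0.7] + [0.0] * 16)
    rec2 = rec.assign(age_years=80.0)
    assert rm.cms_linear_predictor(rec2, spec).iloc[0] == pytest.approx(
        expit(-1.0 + 0.2 * 2.0 + 0.7), abs=1e-9)


def test_split_sizes_and_determinism():
    rec = make_records([{"record_id": f"R{i}"} for i in range(100)])
    part = rm.split_retrain_test(rec, 0.5, seed=3)
    assert (part == "train").sum() == 50 and (part == "test").sum() == 50
    pd.testing.assert_series_equal(part, rm.split_retrain_test(rec, 0.5, seed=3))
    assert not part.equals(rm.split_retrain_test(rec, 0.5, seed=4))
    odd = make_records([{"record_id": f"R{i}"} for i in range(101)])
    p101 = rm.split_retrain_test(odd, 0.5, seed=3)
    assert (p101 == "train").sum() == 51 and (p101 == "test").sum() == 50
    with pytest.raises(ValueError):
        rm.split_retrain_test(rec.iloc[:1], 0.5, seed=0)


def test_youden_worked_example_and_errors():
    assert rm.youden_threshold([0.9, 0.7, 0.4, 0.2], [1, 1, 0, 0]) == pytest.approx(0.7)
    with pytest.raises(ValueError, match="both"):
        rm.youden_threshold([0.1, 0.2], [1, 1])


def _youden_brute(scores, labels):
    best_j, best_t = -np.inf, None
    for t in sorted(set(scores), reverse=True):
        yhat = np.asarray(scores) >= t
        y = np.asarray(labels, dtype=bool)
        sens = (yhat & y).sum() / y.sum()
        spec = (~yhat & ~y).sum() / (~y).sum()
        if sens + spec - 1 > best_j:  # strict: first (largest) t wins ties
            best_j, best_t = sens + spec - 1, t
    return best_t


@pytest.mark.parametrize("seed", range(20))
def test_youden_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 60))
    scores = rng.choice(np.round(rng.random(8), 2), size=n)
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert rm.youden_threshold(scores, labels) == pytest.approx(_youden_brute(scores, labels))


def test_classify_monotone_in_threshold():
    rng = np.random.default_rng(8)
    scores = rng.integers(0, 15, size=200)
    counts = [rm.classify(pd.Series(scores), t)["predicted_high_risk"].sum()
              for t in range(0, 16)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_retrain_deterministic_and_needs_two_classes(labeled_eligible):
    el = labeled_eligible.head(4000)
    y = el["readmit_30d_unplanned"]
    spec1 = rm.retrain_cms(el, y, 20, seed=5)
    spec2 = rm.retrain_cms(el, y, 20, seed=5)
    assert spec1.intercept == spec2.intercept
    assert spec1.coefficients == spec2.coefficients
    assert len(spec1.cv_auc) == 5
    assert spec1.threshold_rule == "youden"
    with pytest.raises(rm.FittingError):
        rm.retrain_cms(el, pd.Series(np.zeros(len(el))), 20, seed=5)
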