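"""Exclusion rules and 30-day readmission labelling."""

import numpy as np
import pandas as pd
import pytest

from readmit_audit.cohort import (apply_exclusions, classify_unplanned,
                                  label_readmissions, observed_rates)
from conftest import brute_force_labels, make_records, random_linked_fixture


def _label(records, **kw):
    labels = apply_exclusions(records)
    return label_readmissions(records, labels, **kw)


@pytest.mark.parametrize("row,reason", [
    ({"age_years": 17}, "age_lt_18"),
    ({"discharge_disposition": "death"}, "died"),
    ({"discharge_disposition": "ama"}, "ama"),
    ({"patient_link_id": None}, "missing_link"),
    ({"los_days": np.nan}, "missing_los"),
])
def test_exclusion_reasons(row, reason):
    labels = apply_exclusions(make_records([row]))
    assert labels.loc[0, "excluded"]
    assert labels.loc[0, "exclusion_reason"] == reason
    assert not labels.loc[0, "eligible_index"]


def test_exclusion_priority_single_reason():
    # a minor who died with broken linkage: missing_link wins the fixed order
    rec = make_records([{"age_years": 16, "discharge_disposition": "death",
                         "patient_link_id": None}])
    labels = apply_exclusions(rec)
    assert labels.loc[0, "exclusion_reason"] == "missing_link"


def test_clean_record_eligible_and_conserved():
    rec = make_records([{"age_years": 40},
                        {"age_years": 17, "record_id": "Rx"},
                        {"discharge_disposition": "ama", "record_id": "Ry"}])
    labels = apply_exclusions(rec)
    assert labels["eligible_index"].tolist() == [True, False, False]
    assert int(labels["excluded"].sum()) + int(labels["eligible_index"].sum()) == len(rec)


@pytest.mark.parametrize("next_admit,expected", [
    (33, True),   # gap 30: inclusive window boundary
    (34, False),  # gap 31: outside
    (4, True),    # gap 1: earliest countable revisit
    (3, False),   # gap 0: same-day transfer, not a readmission
])
def test_window_boundaries(next_admit, expected):
    rec = make_records([
        {"admit_day": 0, "los_days": 3},                      # discharge day 3
        {"admit_day": next_admit, "los_days": 1},
    ])
    out = _label(rec, study_end=400)
    assert bool(out.loc[0, "readmit_30d_all"]) is expected


def test_admit_anchor_and_min_gap_configurable():
    rec = make_records([{"admit_day": 0, "los_days": 5},
                        {"admit_day": 30, "los_days": 1}])
    # discharge anchor: gap 25 -> readmission; admit anchor: gap 30 -> still in
    assert bool(_label(rec, study_end=400).loc[0, "readmit_30d_all"])
    assert bool(_label(rec, anchor="admit", study_end=400).loc[0, "readmit_30d_all"])
    # same-day readmission counts when min_gap=0
    rec2 = make_records([{"admit_day": 0, "los_days": 3}, {"admit_day": 3, "los_days": 1}])
    assert not bool(_label(rec2, study_end=400).loc[0, "readmit_30d_all"])
    assert bool(_label(rec2, min_gap=0, study_end=400).loc[0, "readmit_30d_all"])


def test_unplanned_requires_nonelective_revisit():
    rec = make_records([
        {"admit_day": 0, "los_days": 2},
        {"admit_day": 10, "admission_type": "elective", "planned_flag": 1},
    ])
    out = _label(rec, study_end=400)
    assert bool(out.loc[0, "readmit_30d_all"])
    assert not bool(out.loc[0, "readmit_30d_unplanned"])
    # degenerate predicate: nothing is planned, unplanned == all-cause
    out2 = _label(rec, study_end=400,
                  planned_predicate=lambda r: np.zeros(len(r), dtype=bool))
    assert bool(out2.loc[0, "readmit_30d_unplanned"])


def test_unplanned_looks_past_intermediate_planned_revisit():
    rec = make_records([
        {"admit_day": 0, "los_days": 1},                       # discharge day 1
        {"admit_day": 5, "los_days": 1, "admission_type": "elective"},
        {"admit_day": 20, "los_days": 1, "admission_type": "emergent"},
    ])
    out = _label(rec, study_end=400)
    assert bool(out.loc[0, "readmit_30d_unplanned"])


def test_followup_completeness_flag():
    rec = make_records([{"admit_day": 0, "los_days": 2},
                        {"admit_day": 380, "los_days": 2, "record_id": "Rl"}])
    out = _label(rec, study_end=400)
    assert bool(out.loc[0, "followup_complete"])
    assert not bool(out.loc[1, "followup_complete"])


def test_overlapping_admissions_rejected():
    rec = make_records([{"admit_day": 0, "los_days": 10},
                        {"admit_day": 5, "los_days": 2}])
    with pytest.raises(ValueError, match="overlapping"):
        _label(rec)


def test_classify_unplanned_default_predicate():
    rec = make_records([{"admission_type": "elective"}, {"admission_type": "emergent"}])
    assert classify_unplanned(rec).tolist() == [False, True]


@pytest.mark.parametrize("seed", range(5))
def test_labels_match_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    rec = random_linked_fixture(rng, n_patients=25)
    out = _label(rec, study_end=10_000).set_index("record_id")
    exp_all, exp_unp = brute_force_labels(rec)
    got = out.loc[rec["record_id"]]
    assert (got["readmit_30d_all"].to_numpy() == exp_all).all()
    assert (got["readmit_30d_unplanned"].to_numpy() == exp_unp).all()


def test_window_enlargement_monotone():
    rng = np.random.default_rng(11)
    rec = random_linked_fixture(rng, n_patients=25)
    small = _label(rec, window_days=30, study_end=10_000)["readmit_30d_all"]
    large = _label(rec, window_days=60, study_end=10_000)["readmit_30d_all"]
    assert (large[small] == True).all()  # noqa: E712


def test_observed_rates_direct_ratio_and_groups():
    rows = []
    for i in range(10):
        rows.append({"patient_link_id": f"P{i:06d}", "admit_day": 0, "los_days": 1,
                     "race_group": "black" if i < 4 else "white"})
    # two unplanned readmissions for patients 0 and 4
    rows.append({"patient_link_id": "P000000", "admit_day": 10, "los_days": 1,
                 "race_group": "black"})
    rows.append({"patient_link_id": "P000004", "admit_day": 12, "los_days": 1,
                 "race_group": "white"})
    rec = make_records(rows)
    labels = _label(rec, study_end=400)
    rates = observed_rates(labels, rec, "race").set_index("group")
    assert rates.loc["all", "n"] == 12
    assert rates.loc["all", "rate"] == pytest.approx(2 / 12)
    assert rates.loc["black", "rate"] == pytest.approx(1 / 5)
    assert rates.loc["white", "rate"] == pytest.approx(1 / 7)


def test_observed_rates_empty_cohort_undefined():
    rec = make_records([{"age_years": 10}])
    labels = _label(rec, study_end=400)
    rates = observed_rates(labels, rec, "all")
    assert np.isnan(rates.loc[0, "rate"])
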