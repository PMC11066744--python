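"""Generator: determinism, configured marginals, and exact risk control."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from readmit_audit import synthgen
from readmit_audit.cohort import apply_exclusions, label_readmissions
from readmit_audit.synthgen import ConfigurationError, GeneratorConfig, GroupShift


def _zero_effects_config(**kw):
    """All covariate effects, offsets and injections off: pure-intercept risk."""
    base = dict(
        n_patients=12_000, n_hospitals=20, base_logit=-2.0,
        covariate_effects={k: 0.0 for k in synthgen.SCALAR_COVARIATES},
        condition_effects=np.zeros(20),
        group_offsets={"black": 0.0, "low_income": 0.0},
        group_shifts={"black": GroupShift(), "low_income": GroupShift()},
        planned_revisit_prob=0.0, death_prob=0.0, ama_prob=0.0,
        missing_link_prob=0.0, under18_prob=0.0, seed=7,
    )
    base.update(kw)
    return GeneratorConfig(**base)


def test_seeded_determinism_byte_identical():
    cfg = GeneratorConfig(n_patients=800, n_hospitals=3, seed=1)
    outs = []
    for _ in range(2):
        hospitals = synthgen.generate_hospitals(cfg)
        records, truth = synthgen.generate_discharges(cfg, hospitals)
        buf = io.StringIO()
        synthgen.write_discharges(records, buf)
        outs.append((hospitals, records, truth, buf.getvalue()))
    pd.testing.assert_frame_equal(outs[0][0], outs[1][0])
    pd.testing.assert_frame_equal(outs[0][1], outs[1][1])
    pd.testing.assert_frame_equal(outs[0][2], outs[1][2])
    assert outs[0][3] == outs[1][3]


def test_degenerate_composition_point_mass():
    cfg = GeneratorConfig(n_hospitals=30, hospital_composition=0.5, seed=2)
    hospitals = synthgen.generate_hospitals(cfg)
    assert (hospitals["black_frac_target"] == 0.5).all()


def test_beta_composition_mean():
    cfg = GeneratorConfig(n_hospitals=500, hospital_composition=(2.0, 8.0), seed=3)
    hospitals = synthgen.generate_hospitals(cfg)
    assert abs(hospitals["black_frac_target"].mean() - 0.2) < 0.03


@pytest.mark.parametrize("field,value", [
    ("n_patients", 0),
    ("n_hospitals", -3),
    ("race_mix", (0.5, 0.5)),
    ("race_mix", (0.5, 0.4, 0.2)),
    ("income_low_frac", 1.5),
    ("hospital_composition", (-1.0, 2.0)),
    ("cohort_mix", (1.0, 0.0, 0.0, 0.0, 0.1)),
    ("death_prob", -0.1),
])
def test_invalid_config_names_field(field, value):
    cfg = GeneratorConfig(**{field: value})
    with pytest.raises(ConfigurationError, match=field.split("_")[0]):
        synthgen.generate_hospitals(cfg)


def test_intercept_only_event_rate_matches_logistic():
    """With all effects off, the observed unplanned-revisit rate among
    complete-follow-up index admissions equals logistic(base_logit)."""
    cfg = _zero_effects_config()
    hospitals = synthgen.generate_hospitals(cfg)
    records, truth = synthgen.generate_discharges(cfg, hospitals)
    labels = apply_exclusions(records)
    labels = label_readmissions(records, labels, study_end=cfg.study_days)
    merged = labels.merge(records, on="record_id").merge(truth, on="record_id")
    sub = merged.loc[merged["eligible_index"] & merged["followup_complete"]]
    assert len(sub) > 15_000
    rate = sub["readmit_30d_unplanned"].mean()
    assert abs(rate - expit(-2.0)) < 0.01
    # the label is exactly the fired ground-truth event for these records
    assert (sub["readmit_30d_unplanned"] == sub["event_fired"]).all()
    assert np.allclose(sub["true_event_prob"], expit(-2.0))


def test_no_injections_means_no_exclusions():
    cfg = _zero_effects_config(n_patients=2000)
    hospitals = synthgen.generate_hospitals(cfg)
    records, _ = synthgen.generate_discharges(cfg, hospitals)
    labels = apply_exclusions(records)
    assert int(labels["excluded"].sum()) == 0


def test_marginal_mixtures_converge(small_data):
    config, hospitals, records, _ = small_data
    tol = 3.0 / np.sqrt(len(records))
    race = records["race_group"].value_counts(normalize=True)
    for group, target in zip(synthgen.RACE_GROUPS, config.race_mix):
        assert abs(race.get(group, 0.0) - target) < tol + 0.02
    low = (records["income_group"] == "low").mean()
    assert abs(low - config.income_low_frac) < tol + 0.02


def test_record_structural_invariants(small_data):
    config, hospitals, records, truth = small_data
    assert (records["los_days"] >= 0).all()
    assert (records["discharge_day"] == records["admit_day"] + records["los_days"]).all()
    cond_cols = [c for c in records.columns if c.startswith("cond_")]
    assert len(cond_cols) == config.n_condition_vars
    assert records[cond_cols].isin([0, 1]).all().all()
    assert records["record_id"].is_unique
    assert truth["true_event_prob"].between(0, 1).all()
    # per-patient admissions are temporally ordered and non-nested
    linked = records.dropna(subset=["patient_link_id"])
    by_pat = linked.sort_values(["patient_link_id", "admit_day"])
    prev_disch = by_pat.groupby("patient_link_id")["discharge_day"].shift()
    assert (by_pat["admit_day"] >= prev_disch.fillna(-1)).all()


def test_csv_roundtrip_preserves_missing_linkage(tmp_path, small_data):
    _, _, records, _ = small_data
    path = tmp_path / "records.csv"
    synthgen.write_discharges(records, path)
    back = synthgen.read_discharges(path)
    assert back["patient_link_id"].isna().sum() == records["patient_link_id"].isna().sum()
    assert len(back) == len(records)


def test_group_prevalence_ordering(labeled_eligible):
    """Default conditions give protected groups higher observed event rates."""
    el = labeled_eligible
    rates = el.groupby("race_group")["readmit_30d_unplanned"].mean()
    assert rates["black"] > rates["white"]
    inc = el.groupby("income_group")["readmit_30d_unplanned"].mean()
    assert inc["low"] > inc["other"]
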