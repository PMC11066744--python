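import numpy as np
import pandas as pd
import pytest

from readmit_audit import synthgen
from readmit_audit.cohort import apply_exclusions, label_readmissions

RECORD_DEFAULTS = {
    "patient_link_id": "P000001",
    "hospital_id": "H000",
    "admit_day": 0,
    "los_days": 2,
    "age_years": 50.0,
    "sex": "female",
    "race_group": "white",
    "income_group": "other",
    "payer": "private",
    "admission_type": "emergent",
    "charlson": 0,
    "ed_visits_6mo": 0,
    "admissions_prior_year": 0,
    "oncology_discharge": 0,
    "any_procedure": 0,
    "n_diagnoses": 5,
    "discharge_disposition": "home",
    "planned_flag": 0,
    "cohort_label": "medicine",
}


def make_records(rows):
    """Build a schema-complete discharge table from partial row dicts."""
    full = []
    for i, row in enumerate(rows):
        r = dict(RECORD_DEFAULTS)
        r.update(row)
        r.setdefault("record_id", f"R{i:07d}")
        r["discharge_day"] = r["admit_day"] + r["los_days"]
        full.append(r)
    return pd.DataFrame(full)


def random_linked_fixture(rng, n_patients=30, max_adm=6, window_gap=45):
    """Random linked admissions with valid (non-overlapping) per-patient timing."""
    rows = []
    for p in range(n_patients):
        day = int(rng.integers(0, 40))
        for _ in range(int(rng.integers(1, max_adm + 1))):
            los = int(rng.integers(0, 9))
            rows.append({
                "patient_link_id": None if rng.random() < 0.05 else f"P{p:06d}",
                "admit_day": day,
                "los_days": los,
                "admission_type": "elective" if rng.random() < 0.2 else "emergent",
            })
            day += los + int(rng.integers(0, window_gap))
    return make_records(rows)


def brute_force_labels(records, window_days=30, min_gap=1):
    """O(n^2) all-pairs readmission oracle (independent of the implementation)."""
    n = len(records)
    pid = records["patient_link_id"].to_numpy(dtype=object)
    admit = records["admit_day"].to_numpy()
    disch = records["discharge_day"].to_numpy()
    unplanned = (records["admission_type"] != "elective").to_numpy()
    linked = np.array([p is not None and not pd.isna(p) for p in pid])
    same = (pid[:, None] == pid[None, :]) & linked[:, None] & linked[None, :]
    np.fill_diagonal(same, False)
    gap = admit[None, :] - disch[:, None]
    inwin = same & (gap >= min_gap) & (gap <= window_days)
    return inwin.any(axis=1), (inwin & unplanned[None, :]).any(axis=1)


def pair_count_auc(scores, labels):
    """Brute-force Mann-Whitney AUC over all positive-negative pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def small_config():
    return synthgen.GeneratorConfig(n_patients=4000, n_hospitals=25, seed=42)


@pytest.fixture(scope="session")
def small_data(small_config):
    hospitals = synthgen.generate_hospitals(small_config)
    records, truth = synthgen.generate_discharges(small_config, hospitals)
    return small_config, hospitals, records, truth


@pytest.fixture(scope="session")
def labeled_eligible(small_data):
    config, hospitals, records, truth = small_data
    labels = apply_exclusions(records)
    labels = label_readmissions(records, labels, study_end=config.study_days)
    merged = labels.merge(records, on="record_id", how="left", validate="1:1")
    return merged.loc[merged["eligible_index"]].reset_index(drop=True)
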