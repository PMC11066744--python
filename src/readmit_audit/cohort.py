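"""Cohort determination: exclusions and 30-day readmission labelling.

Implements the standard administrative-data readmission workflow: drop
admissions that cannot serve as index admissions (minors, in-hospital
deaths, against-medical-advice discharges, broken linkage, missing length
of stay), then, for every eligible index admission, look for a subsequent
admission by the same patient inside the follow-up window.  Every eligible
admission is an index admission; a revisit can itself be an index admission
for its own window.

Window semantics (all configurable): the window is anchored at the index
discharge day, a revisit counts when its admission day falls ``min_gap`` to
``window_days`` days after the anchor, inclusive.  Same-day re-admission
(gap 0) is treated as a transfer/continuation, not a readmission.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUSION_PRIORITY",
    "apply_exclusions",
    "classify_unplanned",
    "label_readmissions",
    "observed_rates",
    "AXIS_COLUMNS",
]

logger = logging.getLogger(__name__)

#: fixed priority order: a record failing several checks gets the first reason
EXCLUSION_PRIORITY = ("missing_link", "missing_los", "age_lt_18", "died", "ama")

AXIS_COLUMNS = {"race": "race_group", "income": "income_group", "payer": "payer"}

_REQUIRED_COLUMNS = (
    "record_id", "patient_link_id", "admit_day", "los_days", "discharge_day",
    "age_years", "discharge_disposition", "admission_type",
)


def _validate_schema(records: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"discharge table is missing required columns: {missing}")
    bad = records.loc[records["los_days"].notna() & (records["los_days"] < 0), "record_id"]
    if len(bad):
        raise ValueError(f"negative los_days for records: {list(bad.head(5))}")


def apply_exclusions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-record exclusion flags with a single primary reason.

    Returns a frame keyed by ``record_id`` with ``excluded``,
    ``exclusion_reason`` (None when retained) and ``eligible_index``.
    """
    _validate_schema(records)
    checks = {
        "missing_link": records["patient_link_id"].isna().to_numpy(),
        "missing_los": records["los_days"].isna().to_numpy(),
        "age_lt_18": (records["age_years"] < 18).to_numpy(),
        "died": (records["discharge_disposition"] == "death").to_numpy(),
        "ama": (records["discharge_disposition"] == "ama").to_numpy(),
    }
    reason = np.select([checks[r] for r in EXCLUSION_PRIORITY], EXCLUSION_PRIORITY,
                       default=None)
    excluded = reason != None  # noqa: E711  (elementwise against object array)
    return pd.DataFrame({
        "record_id": records["record_id"].to_numpy(),
        "excluded": excluded,
        "exclusion_reason": reason,
        "eligible_index": ~excluded,
    })


def classify_unplanned(records: pd.DataFrame, planned_predicate=None) -> pd.Series:
    """Whether each admission, viewed as a revisit, counts as unplanned.

    ``planned_predicate(records) -> boolean array`` marks planned revisits;
    the default treats elective admissions as planned.  The full
    claims-based planned-readmission algorithm is out of scope; any
    predicate over the record table can be plugged in instead.
    """
    if planned_predicate is None:
        planned = (records["admission_type"] == "elective").to_numpy()
    else:
        planned = np.asarray(planned_predicate(records), dtype=bool)
        if planned.shape != (len(records),):
            raise ValueError("planned_predicate must return one flag per record")
    return pd.Series(~planned, index=records.index, name="is_unplanned")


def label_readmissions(records: pd.DataFrame, labels: pd.DataFrame, *,
                       window_days: int = 30, anchor: str = "discharge",
                       min_gap: int = 1, study_end: int | None = None,
                       planned_predicate=None) -> pd.DataFrame:
    """Attach 30-day all-cause and unplanned readmission outcomes to labels.

    A subsequent admission is any linked record of the same patient whose
    admission day falls in ``[anchor_day + min_gap, anchor_day + window_days]``;
    all linked records count as potential revisits, including ones excluded
    as index admissions (e.g. a readmission ending in death is still a
    readmission).  ``followup_complete`` is False when the window extends
    past ``study_end`` (default: the latest discharge day observed).
    """
    if anchor not in ("discharge", "admit"):
        raise ValueError(f"anchor must be 'discharge' or 'admit', got {anchor!r}")
    if study_end is None:
        study_end = int(records["discharge_day"].max())

    out = labels.set_index("record_id").copy()
    out["followup_complete"] = False
    out["readmit_30d_all"] = False
    out["readmit_30d_unplanned"] = False
    out["days_to_next_admission"] = pd.array([pd.NA] * len(out), dtype="Int64")

    linked = records.loc[records["patient_link_id"].notna()].copy()
    if linked.empty:
        return out.reset_index()
    linked["is_unplanned"] = classify_unplanned(linked, planned_predicate)
    linked = linked.sort_values(["patient_link_id", "admit_day", "discharge_day"],
                                kind="mergesort")

    pat = linked["patient_link_id"].to_numpy()
    admit = linked["admit_day"].to_numpy(dtype=np.int64)
    disch = linked["discharge_day"].to_numpy(dtype=np.int64)
    unplanned = linked["is_unplanned"].to_numpy(dtype=np.int64)
    n = len(linked)

    same_next = np.zeros(n, dtype=bool)
    same_next[:-1] = pat[:-1] == pat[1:]
    overlap = same_next[:-1] & (admit[1:] < disch[:-1]) if n > 1 else np.array([], bool)
    if overlap.any():
        bad = linked["record_id"].to_numpy()[:-1][overlap]
        raise ValueError(f"overlapping admissions within patient for records: {list(bad[:5])}")

    # composite key makes per-patient searchsorted a single global call
    pat_code = pd.factorize(pat)[0].astype(np.int64)
    big = int(max(admit.max(), disch.max()) + window_days + min_gap + 2)
    key = pat_code * big + admit
    anchor_day = disch if anchor == "discharge" else admit
    lo = np.searchsorted(key, pat_code * big + np.minimum(anchor_day + min_gap, big - 1), "left")
    hi = np.searchsorted(key, pat_code * big + np.minimum(anchor_day + window_days, big - 1), "right")

    readmit_all = hi > lo
    cs = np.concatenate([[0], np.cumsum(unplanned)])
    readmit_unp = (cs[hi] - cs[lo]) > 0

    days_next = np.full(n, -1, dtype=np.int64)
    if n > 1:
        days_next[:-1] = np.where(same_next[:-1], admit[1:] - disch[:-1], -1)

    idx = linked["record_id"].to_numpy()
    out.loc[idx, "readmit_30d_all"] = readmit_all
    out.loc[idx, "readmit_30d_unplanned"] = readmit_unp
    dtn = pd.array(days_next, dtype="Int64")
    dtn[days_next < 0] = pd.NA
    out.loc[idx, "days_to_next_admission"] = dtn

    all_disch = records.set_index("record_id")["discharge_day"]
    out["followup_complete"] = (all_disch.reindex(out.index) + window_days) <= study_end
    return out.reset_index()


def observed_rates(labels: pd.DataFrame, records: pd.DataFrame,
                   grouping_axis: str = "all", *,
                   outcome: str = "readmit_30d_unplanned",
                   require_complete_followup: bool = False) -> pd.DataFrame:
    """Observed readmission rate per group: events / eligible index admissions."""
    merged = labels.merge(records, on="record_id", how="left", validate="1:1")
    mask = merged["eligible_index"].to_numpy(dtype=bool)
    if require_complete_followup:
        mask &= merged["followup_complete"].to_numpy(dtype=bool)
    sub = merged.loc[mask]

    def _row(group, frame):
        n = len(frame)
        k = int(frame[outcome].sum())
        if n == 0:
            logger.warning("observed_rates: empty group %r, rate undefined", group)
            return {"group": group, "n": 0, "n_events": 0, "rate": np.nan}
        return {"group": group, "n": n, "n_events": k, "rate": k / n}

    rows = [_row("all", sub)]
    if grouping_axis != "all":
        col = AXIS_COLUMNS.get(grouping_axis, grouping_axis)
        if col not in sub.columns:
            raise ValueError(f"unknown grouping axis {grouping_axis!r}")
        for group, frame in sub.groupby(col, sort=True):
            rows.append(_row(group, frame))
    return pd.DataFrame(rows)
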