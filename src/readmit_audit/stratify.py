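"""Hospital-level stratification of bias measures.

Two views of how racial bias varies across care settings: per-hospital
FNR/FPR differences (scatter data, with the quadrant convention that
quadrant I means protected-group FPR higher and reference-group FNR higher),
and cumulative hospital-composition bins — for each threshold x, admissions
from all hospitals whose observed Black-patient share exceeds x are pooled
and the differences recomputed with 95% confidence intervals.  Bins are
cumulative: a hospital serving 25% Black patients contributes to the >0,
>10% and >20% bins.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .fairness import confusion_by_group, error_rates

__all__ = [
    "DEFAULT_BIN_THRESHOLDS",
    "per_hospital_bias",
    "composition_bins",
    "stratum_ci",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_THRESHOLDS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)


def _quadrant(diff_fnr: float, diff_fpr: float) -> str:
    if diff_fnr == 0 or diff_fpr == 0 or np.isnan(diff_fnr) or np.isnan(diff_fpr):
        return "axis"
    if diff_fpr > 0:
        return "I" if diff_fnr < 0 else "II"
    return "III" if diff_fnr > 0 else "IV"


def per_hospital_bias(frame: pd.DataFrame, *, protected: str = "black",
                      reference: str = "white", group_col: str = "race_group",
                      outcome_col: str = "readmit_30d_unplanned") -> pd.DataFrame:
    """Within-hospital FNR/FPR differences (protected minus reference).

    ``frame`` has one row per analyzed admission with ``hospital_id``,
    ``predicted_high_risk``, the outcome and group columns, and
    ``race_group`` (used for the observed Black share regardless of axis).
    Hospitals lacking either group or with an undefined rate are returned
    flagged via ``skipped_reason`` and carry NaN differences.
    """
    rows = []
    for hosp, sub in frame.groupby("hospital_id", sort=True):
        black_frac = float((sub["race_group"] == "black").mean())
        row = {"hospital_id": hosp, "n_admissions": len(sub), "black_frac_observed": black_frac,
               "diff_fnr": np.nan, "diff_fpr": np.nan, "quadrant": "axis",
               "skipped_reason": None}
        g = sub[group_col].to_numpy()
        if not ((g == protected).any() and (g == reference).any()):
            row["skipped_reason"] = "missing_group"
            rows.append(row)
            continue
        conf = confusion_by_group(sub["predicted_high_risk"].to_numpy(),
                                  sub[outcome_col].to_numpy(), g).set_index("group")
        fnr_p, fpr_p, _ = error_rates(conf.loc[protected])
        fnr_r, fpr_r, _ = error_rates(conf.loc[reference])
        dfnr, dfpr = fnr_p - fnr_r, fpr_p - fpr_r
        if np.isnan(dfnr) or np.isnan(dfpr):
            row["skipped_reason"] = "undefined_rate"
            rows.append(row)
            continue
        row.update(diff_fnr=dfnr, diff_fpr=dfpr, quadrant=_quadrant(dfnr, dfpr))
        rows.append(row)
    return pd.DataFrame(rows)


def stratum_ci(p1: float, n1: int, p2: float, n2: int,
               method: str = "wald") -> tuple[float, float, float]:
    """(point, lo, hi) 95% interval for the difference of two proportions.

    ``wald``: diff +/- 1.96*sqrt(p1 q1/n1 + p2 q2/n2), clamped to [-1, 1]
    (degenerate proportions give a zero-width Wald term).  ``newcombe``:
    hybrid of the two Wilson score intervals.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both group denominators must be positive")
    diff = p1 - p2
    z = stats.norm.ppf(0.975)
    if method == "wald":
        se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
        lo, hi = diff - z * se, diff + z * se
        if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
            logger.warning("stratum_ci: degenerate proportion; Wald interval unreliable")
    elif method == "newcombe":
        def wilson(p, n):
            den = 1 + z**2 / n
            center = (p + z**2 / (2 * n)) / den
            half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / den
            return center - half, center + half
        l1, u1 = wilson(p1, n1)
        l2, u2 = wilson(p2, n2)
        lo, hi = diff - np.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2), \
            diff + np.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(diff), float(max(lo, -1.0)), float(min(hi, 1.0))


def composition_bins(frame: pd.DataFrame, hospital_bias: pd.DataFrame, *,
                     thresholds=DEFAULT_BIN_THRESHOLDS, protected: str = "black",
                     reference: str = "white", group_col: str = "race_group",
                     outcome_col: str = "readmit_30d_unplanned",
                     model_id: str = "model", ci_method: str = "wald") -> pd.DataFrame:
    """Pooled bias measures with 95% CIs in cumulative composition bins.

    For each threshold, admissions of hospitals with observed Black share
    strictly above it are pooled and the FNR/FPR differences recomputed on
    the pooled confusion counts.  Empty bins (no hospitals, or a missing
    group in the pooled data) are omitted with a note.
    """
    frac = hospital_bias.set_index("hospital_id")["black_frac_observed"]
    rows = []
    for t in thresholds:
        hosps = frac.index[frac > t]
        sub = frame[frame["hospital_id"].isin(hosps)]
        if len(hosps) == 0 or len(sub) == 0:
            logger.warning("composition bin >%s omitted: empty", t)
            continue
        g = sub[group_col].to_numpy()
        if not ((g == protected).any() and (g == reference).any()):
            logger.warning("composition bin >%s omitted: missing group", t)
            continue
        conf = confusion_by_group(sub["predicted_high_risk"].to_numpy(),
                                  sub[outcome_col].to_numpy(), g).set_index("group")
        cp, cr = conf.loc[protected], conf.loc[reference]
        row = {"model_id": model_id, "min_black_frac": t,
               "n_hospitals": int(len(hosps)), "n_admissions": int(len(sub))}
        pos_p, pos_r = cp["tp"] + cp["fn"], cr["tp"] + cr["fn"]
        neg_p, neg_r = cp["fp"] + cp["tn"], cr["fp"] + cr["tn"]
        if min(pos_p, pos_r, neg_p, neg_r) == 0:
            logger.warning("composition bin >%s omitted: undefined rate", t)
            continue
        d, lo, hi = stratum_ci(cp["fn"] / pos_p, pos_p, cr["fn"] / pos_r, pos_r,
                               method=ci_method)
        row.update(diff_fnr=d, fnr_ci_low=lo, fnr_ci_high=hi)
        d, lo, hi = stratum_ci(cp["fp"] / neg_p, neg_p, cr["fp"] / neg_r, neg_r,
                               method=ci_method)
        row.update(diff_fpr=d, fpr_ci_low=lo, fpr_ci_high=hi)
        rows.append(row)
    return pd.DataFrame(rows)
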