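"""Per-group predictive performance: AUC, Brier statistic, Hosmer-Lemeshow,
and observed vs predicted readmission rates.

The Brier statistic has two modes.  ``probability`` is the textbook mean
squared error of a probabilistic prediction; ``binary`` (the default used in
reporting) squares the dichotomized high-risk call against the outcome and
is therefore identical to the 0-1 loss — the operational definition under
which point-score models (LACE, HOSPITAL) are usually reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = ["auc", "brier", "hosmer_lemeshow", "predicted_rate", "performance_table"]

logger = logging.getLogger(__name__)


def auc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties count 1/2)."""
    y = np.asarray(labels, dtype=int)
    if len(y) == 0 or y.min() == y.max():
        logger.warning("auc undefined: only one outcome class present")
        return float("nan")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def brier(predictions, labels, mode: str = "binary") -> float:
    """Mean squared difference between prediction and outcome.

    ``mode='probability'`` expects scores in [0, 1]; ``mode='binary'``
    expects (or dichotomizes to) 0/1 high-risk calls and equals the 0-1 loss.
    """
    y = np.asarray(labels, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if mode == "probability":
        if (p < 0).any() or (p > 1).any():
            raise ValueError(
                "probability-mode Brier needs scores in [0, 1]; point scores should "
                "use mode='binary' or be normalized first")
        return float(np.mean((p - y) ** 2))
    if mode == "binary":
        b = p.astype(bool).astype(float)
        return float(np.mean((b - y) ** 2))
    raise ValueError(f"mode must be 'probability' or 'binary', got {mode!r}")


def hosmer_lemeshow(probabilities, labels, g: int = 10) -> tuple[float, float, int]:
    """Hosmer-Lemeshow goodness-of-fit test.

    Records are binned into ``g`` quantile groups of predicted risk (ties
    share a bin, so fewer bins can result); the statistic sums
    (O-E)^2/E over events and non-events per bin and is referred to a
    chi-square with (bins - 2) degrees of freedom.  Bins with zero expected
    events or non-events are merged with their neighbor.  Returns
    ``(stat, p, n_bins_used)``.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(p) < g:
        raise ValueError(f"need at least g={g} records, got {len(p)}")
    bins = pd.qcut(p, g, labels=False, duplicates="drop")
    tab = pd.DataFrame({"p": p, "y": y, "bin": bins}).groupby("bin").agg(
        n=("y", "size"), obs=("y", "sum"), exp=("p", "sum"))
    # merge degenerate bins upward (E of events or non-events == 0)
    rows = tab.to_numpy().tolist()
    merged = []
    for row in rows:
        if merged and (merged[-1][2] <= 0 or merged[-1][0] - merged[-1][2] <= 0):
            merged[-1] = [a + b for a, b in zip(merged[-1], row)]
        else:
            merged.append(list(row))
    while len(merged) > 1 and (merged[-1][2] <= 0 or merged[-1][0] - merged[-1][2] <= 0):
        last = merged.pop()
        merged[-1] = [a + b for a, b in zip(merged[-1], last)]
    if len(merged) < len(rows):
        logger.warning("hosmer_lemeshow: merged %d degenerate bin(s)", len(rows) - len(merged))
    stat = 0.0
    for n, obs, exp in merged:
        exp0 = n - exp
        stat += (obs - exp) ** 2 / exp + ((n - obs) - exp0) ** 2 / exp0
    df = max(len(merged) - 2, 1)
    return float(stat), float(stats.chi2.sf(stat, df)), len(merged)


def predicted_rate(predictions: pd.DataFrame, kind: str) -> float:
    """Model-predicted readmission rate for a group.

    Point models: fraction of the group classified high-risk.  Logistic
    models: mean predicted probability.
    """
    if len(predictions) == 0:
        logger.warning("predicted_rate: empty group")
        return float("nan")
    if kind == "points":
        return float(predictions["predicted_high_risk"].mean())
    if kind == "logistic":
        return float(predictions["score"].mean())
    raise ValueError(f"kind must be 'points' or 'logistic', got {kind!r}")


def performance_table(frame: pd.DataFrame, model_id: str, kind: str,
                      grouping_axis: str, group_col: str | None, *,
                      outcome_col: str = "readmit_30d_unplanned",
                      brier_mode: str = "binary", hl_bins: int = 10) -> pd.DataFrame:
    """Per-group performance rows for one model.

    ``frame`` holds one row per analyzed admission with ``score``,
    ``predicted_high_risk``, the outcome column, and (optionally) the group
    column.  An 'all' row is always included.
    """
    def _metrics(sub: pd.DataFrame, group: str) -> dict:
        y = sub[outcome_col].to_numpy(dtype=int)
        row = {"grouping_axis": grouping_axis, "group": group, "n": len(sub),
               "model_id": model_id}
        if len(sub) == 0:
            return {**row, "auc": np.nan, "brier": np.nan, "hl_stat": np.nan,
                    "hl_p": np.nan, "observed_rate": np.nan, "predicted_rate": np.nan}
        row["auc"] = auc(sub["score"], y)
        if brier_mode == "probability" and kind == "logistic":
            row["brier"] = brier(sub["score"], y, mode="probability")
        else:
            row["brier"] = brier(sub["predicted_high_risk"], y, mode="binary")
        probs = sub["score"] if kind == "logistic" else None
        if probs is not None and len(sub) >= hl_bins and 0 < y.sum() < len(y):
            stat, pval, _ = hosmer_lemeshow(probs, y, g=hl_bins)
            row["hl_stat"], row["hl_p"] = stat, pval
        else:
            row["hl_stat"], row["hl_p"] = np.nan, np.nan
        row["observed_rate"] = float(np.mean(y))
        row["predicted_rate"] = predicted_rate(sub, kind)
        return row

    rows = [_metrics(frame, "all")]
    if group_col is not None:
        for group, sub in frame.groupby(group_col, sort=True):
            rows.append(_metrics(sub, group))
    return pd.DataFrame(rows)
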