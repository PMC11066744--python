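"""Group fairness measures for binary risk classification.

Error-rate parity (equalized odds) is operationalized as between-group
differences of the false negative rate, false positive rate and 0-1 loss,
with a fixed sign convention: protected minus reference (Black minus White;
low-income minus other-income).  Inequality of the classification outcome is
additionally summarized by the generalized entropy index over per-record
benefits b = prediction - outcome + 1 (0 = false negative, 1 = correct,
2 = false positive); the between-group variant replaces each record's
benefit with its group mean, so it is zero whenever group mean benefits
coincide even if error compositions differ.

Significance of a rate difference is assessed with a two-tailed Welch t test
on the per-admission error indicators (restricted to actual positives for
the FNR, actual negatives for the FPR, and all records for the 0-1 loss).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "confusion_by_group",
    "error_rates",
    "rate_difference",
    "benefit_vector",
    "generalized_entropy",
    "between_group_gei",
    "difference_test",
    "bias_table",
    "holm_adjust",
]

logger = logging.getLogger(__name__)


def confusion_by_group(pred_high: np.ndarray, outcome: np.ndarray,
                       groups: np.ndarray) -> pd.DataFrame:
    """Confusion counts (tp, fp, tn, fn) per group.

    Positives are observed unplanned 30-day readmissions; a positive
    prediction is a high-risk classification.
    """
    yhat = np.asarray(pred_high, dtype=bool)
    y = np.asarray(outcome, dtype=bool)
    g = np.asarray(groups)
    if not (len(yhat) == len(y) == len(g)):
        raise ValueError("predictions, outcomes and groups must align")
    rows = []
    for grp in pd.unique(g):
        m = g == grp
        rows.append({
            "group": grp,
            "tp": int((yhat & y & m).sum()),
            "fp": int((yhat & ~y & m).sum()),
            "tn": int((~yhat & ~y & m).sum()),
            "fn": int((~yhat & y & m).sum()),
        })
    df = pd.DataFrame(rows)
    df["n"] = df[["tp", "fp", "tn", "fn"]].sum(axis=1)
    return df


def error_rates(conf: pd.Series | dict) -> tuple[float, float, float]:
    """(FNR, FPR, 0-1 loss) from one group's confusion counts.

    FNR = fn/(fn+tp); FPR = fp/(fp+tn); 0-1 loss = (fp+fn)/n.  A rate with a
    zero denominator is returned as NaN with a warning.
    """
    tp, fp, tn, fn = (conf["tp"], conf["fp"], conf["tn"], conf["fn"])
    n = tp + fp + tn + fn

    def _safe(num, den, name):
        if den == 0:
            logger.warning("error_rates: %s undefined (zero denominator)", name)
            return float("nan")
        return num / den

    return (_safe(fn, fn + tp, "fnr"), _safe(fp, fp + tn, "fpr"), _safe(fp + fn, n, "loss"))


def rate_difference(protected_rate: float, reference_rate: float) -> float:
    """Protected minus reference (B-W, L-O sign convention)."""
    return protected_rate - reference_rate


def benefit_vector(pred_high, outcome) -> np.ndarray:
    """Per-record benefit b = prediction - outcome + 1, in {0, 1, 2}."""
    yhat = np.asarray(pred_high, dtype=int)
    y = np.asarray(outcome, dtype=int)
    return yhat - y + 1


def generalized_entropy(benefits, alpha: float = 2.0) -> float:
    """Generalized entropy index GE(alpha) of a benefit vector.

    GE(a) = 1/(n*a*(a-1)) * sum((b_i/mu)^a - 1); nonnegative, zero iff all
    benefits are equal, scale-invariant.  Undefined (NaN, with a warning)
    when the mean benefit is zero.
    """
    if alpha in (0.0, 1.0):
        raise ValueError("alpha in {0, 1} requires the limit forms; use another order")
    b = np.asarray(benefits, dtype=float)
    mu = b.mean()
    if mu <= 0:
        logger.warning("generalized_entropy undefined: mean benefit <= 0")
        return float("nan")
    return float(np.mean((b / mu) ** alpha - 1.0) / (alpha * (alpha - 1.0)))


def between_group_gei(benefits, groups, alpha: float = 2.0) -> float:
    """Between-group GEI: each benefit replaced by its group mean."""
    b = np.asarray(benefits, dtype=float)
    g = np.asarray(groups)
    if len(pd.unique(g)) < 2:
        raise ValueError("between_group_gei needs at least 2 groups")
    means = pd.Series(b).groupby(pd.Series(g)).transform("mean").to_numpy()
    return generalized_entropy(means, alpha=alpha)


def difference_test(indicators_a, indicators_b) -> float:
    """Two-tailed Welch t test p-value for a difference of error rates.

    Inputs are per-record 0/1 error indicators for the two groups (actual
    positives for the FNR test, actual negatives for FPR, everyone for 0-1
    loss).  Groups with fewer than 2 records skip the test (NaN, warning);
    identical zero-variance samples give p = 1 by convention.
    """
    a = np.asarray(indicators_a, dtype=float)
    b = np.asarray(indicators_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        logger.warning("difference_test skipped: group with < 2 eligible records")
        return float("nan")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (optional; reporting default applies none)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def bias_table(pred_high, outcome, groups, protected, reference, *,
               model_id: str = "model", axis: str = "race",
               alpha: float = 2.0) -> dict:
    """One bias-report row comparing a protected and a reference group.

    Per-group FNR/FPR/0-1 loss, their protected-minus-reference differences,
    the between-group GEI over the two groups' benefits (order ``alpha``
    recorded), and Welch-t p-values for each difference.
    """
    yhat = np.asarray(pred_high, dtype=bool)
    y = np.asarray(outcome, dtype=bool)
    g = np.asarray(groups)

    conf = confusion_by_group(yhat, y, g).set_index("group")
    row = {"model_id": model_id, "axis": axis, "protected": protected,
           "reference": reference, "gei_alpha": alpha}
    rates = {}
    for name, grp in (("protected", protected), ("reference", reference)):
        if grp not in conf.index:
            raise ValueError(f"group {grp!r} absent from data")
        fnr, fpr, loss = error_rates(conf.loc[grp])
        rates[name] = (fnr, fpr, loss)
        row[f"fnr_{name}"] = fnr
        row[f"fpr_{name}"] = fpr
        row[f"loss_{name}"] = loss
        row[f"n_{name}"] = int(conf.loc[grp, "n"])
    row["diff_fnr"] = rate_difference(rates["protected"][0], rates["reference"][0])
    row["diff_fpr"] = rate_difference(rates["protected"][1], rates["reference"][1])
    row["diff_01"] = rate_difference(rates["protected"][2], rates["reference"][2])

    both = (g == protected) | (g == reference)
    row["gei_between"] = between_group_gei(benefit_vector(yhat[both], y[both]), g[both],
                                           alpha=alpha)
    mp, mr = g == protected, g == reference
    fn_ind = (~yhat).astype(int)
    fp_ind = yhat.astype(int)
    err_ind = (yhat != y).astype(int)
    row["p_fnr"] = difference_test(fn_ind[mp & y], fn_ind[mr & y])
    row["p_fpr"] = difference_test(fp_ind[mp & ~y], fp_ind[mr & ~y])
    row["p_01"] = difference_test(err_ind[mp], err_ind[mr])
    return row
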