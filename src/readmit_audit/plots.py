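"""Optional matplotlib views of the stratified bias outputs."""

from __future__ import annotations

import pandas as pd

QUADRANT_NOTE = "x: FNR difference (B-W); y: FPR difference (B-W); lines mark equality"


def hospital_scatter(hospital_bias: pd.DataFrame, ax=None, label: str | None = None):
    """Per-hospital FNR vs FPR difference scatter with equality lines at 0."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sub = hospital_bias.dropna(subset=["diff_fnr", "diff_fpr"])
    ax.scatter(sub["diff_fnr"], sub["diff_fpr"], s=12 + 0.002 * sub["n_admissions"],
               alpha=0.6, label=label)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("FNR difference (protected - reference)")
    ax.set_ylabel("FPR difference (protected - reference)")
    return ax


def composition_bin_plot(bins: pd.DataFrame, measure: str = "diff_fnr", ax=None,
                         label: str | None = None):
    """Binned bias measure with 95% CI error bars against the bin threshold."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    lo = bins[f"{measure.split('_')[1]}_ci_low"]
    hi = bins[f"{measure.split('_')[1]}_ci_high"]
    ax.errorbar(bins["min_black_frac"], bins[measure],
                yerr=[bins[measure] - lo, hi - bins[measure]],
                fmt="o-", capsize=3, label=label)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("hospital Black-patient share threshold (cumulative bins, > x)")
    ax.set_ylabel(measure.replace("_", " "))
    return ax
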