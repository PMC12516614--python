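"""Basic plots: spline dose-response curve and decomposition bar chart."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_dose_response(curve: pd.DataFrame, ax=None, knots=None):
    """HR vs cups with its pointwise confidence band.

    ``curve`` is the grid returned by
    :func:`~lifegain.cox.spline_dose_response` (cups, hr, ci_lo, ci_hi).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["cups"], curve["hr"], color="tab:blue")
    ax.fill_between(curve["cups"], curve["ci_lo"], curve["ci_hi"],
                    alpha=0.25, color="tab:blue", linewidth=0)
    ax.axhline(1.0, color="grey", linestyle="--", linewidth=0.8)
    if knots is not None:
        for k in knots:
            ax.axvline(k, color="grey", linestyle=":", linewidth=0.6)
    ax.set_xlabel("coffee consumption (cups/day)")
    ax.set_ylabel("hazard ratio")
    return ax


def plot_decomposition(decomposition: pd.DataFrame, ax=None):
    """Stacked per-age cause contributions to a life-expectancy difference.

    ``decomposition`` is the age-indexed table from
    :func:`~lifegain.decompose.decompose_gain`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ages = decomposition.index.to_numpy()
    bottom_pos = ages * 0.0
    bottom_neg = ages * 0.0
    colors = {"cvd": "tab:red", "cancer": "tab:purple", "other": "tab:grey"}
    for cause in ("cvd", "cancer", "other"):
        vals = decomposition[cause].to_numpy()
        bottom = [bn if v < 0 else bp for v, bp, bn in zip(vals, bottom_pos, bottom_neg)]
        ax.bar(ages, vals, bottom=bottom, label=cause, color=colors[cause], width=0.9)
        bottom_pos = bottom_pos + vals.clip(min=0)
        bottom_neg = bottom_neg + vals.clip(max=0)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("contribution to life gain (years)")
    ax.legend(title="cause of death", frameon=False)
    return ax
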