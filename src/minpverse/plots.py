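"""Standard figures for the two simulation studies."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

_COLORS = {"none": "tab:red", "minp": "tab:green", "bonferroni": "tab:blue"}
_LABELS = {"none": "unadjusted", "minp": "minP", "bonferroni": "Bonferroni"}


def plot_fwer(table: pd.DataFrame, ax=None):
    """FWER vs n per method, with Newcombe CI ribbons and the nominal level."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    alpha = float(table["alpha"].iloc[0])
    for method, sub in table.groupby("method"):
        sub = sub.sort_values("n")
        ax.plot(sub["n"], sub["fwer"], marker="o",
                color=_COLORS.get(method), label=_LABELS.get(method, method))
        ax.fill_between(sub["n"], sub["ci_lower"], sub["ci_upper"],
                        color=_COLORS.get(method), alpha=0.2, linewidth=0)
    ax.axhline(alpha, color="red", linestyle="--", linewidth=1)
    ax.set_xlabel("sample size n")
    ax.set_ylabel("family-wise error rate")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax.figure


def plot_proportions(table: pd.DataFrame, axes=None):
    """Mean fraction of significant specifications vs n, one panel per alpha."""
    alphas = sorted(table["alpha"].unique())
    if axes is None:
        _, axes = plt.subplots(1, len(alphas), figsize=(4 * len(alphas), 3.5),
                               sharey=True)
    try:
        axes = list(axes)
    except TypeError:
        axes = [axes]
    for ax, alpha in zip(axes, alphas):
        sub_a = table[table["alpha"] == alpha]
        for method, sub in sub_a.groupby("method"):
            sub = sub.sort_values("n")
            ax.plot(sub["n"], sub["mean_significant_fraction"], marker="o",
                    color=_COLORS.get(method), label=_LABELS.get(method, method))
        ax.set_title(f"alpha = {alpha:g}")
        ax.set_xlabel("sample size n")
        ax.set_ylim(0, 1)
    axes[0].set_ylabel("mean fraction significant")
    axes[0].legend()
    return axes[0].figure
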