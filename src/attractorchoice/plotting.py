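"""Figures: PI distributions per block and direction-split choice curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_perseveration_distributions", "plot_perseveration_curves"]


def plot_perseveration_distributions(pi_table: pd.DataFrame, ax=None):
    """Violin + box plot of the perseveration index per experimental block."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    blocks = list(pi_table.columns)
    data = [pi_table[b].dropna().to_numpy() for b in blocks]
    ax.violinplot(data, showextrema=False)
    ax.boxplot(data, widths=0.15)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(np.arange(1, len(blocks) + 1), blocks)
    ax.set_ylabel("perseveration index")
    return ax


def plot_perseveration_curves(curves: pd.DataFrame, title: str = "", ax=None):
    """Direction-split mean %LF curves with standard-error bars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for direction, grp in curves.groupby("direction"):
        grp = grp.sort_values("bin")
        ax.errorbar(
            grp["bin"], grp["pct_lf"], yerr=grp["se"], marker="o", capsize=2,
            label=direction,
        )
    ax.set_xlabel("manipulation point / interval")
    ax.set_ylabel("% LF choices")
    ax.set_ylim(-5, 105)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
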