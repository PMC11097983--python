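"""Report figures: group timecourses and potentiated-proportion bars."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")  # headless report generation
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_group_timecourse", "plot_proportion_bars"]


def plot_group_timecourse(timecourse: pd.DataFrame, ax=None):
    """Mean +/- SEM normalized response per block, one line per condition.

    ``timecourse`` is the output of :func:`cspot.stats.group_timecourse`
    (columns condition, block, mean, sem, n).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for condition, g in timecourse.groupby("condition", sort=False):
        g = g.sort_values("block")
        ax.errorbar(
            g["block"], g["mean"], yerr=g["sem"], fmt="o-", capsize=2, label=str(condition)
        )
    ax.axhline(100.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("block")
    ax.set_ylabel("response magnitude (% of baseline)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_proportion_bars(proportions: Mapping[str, tuple[int, int]], ax=None):
    """Percent of channels potentiated per condition.

    ``proportions`` maps condition name to (potentiated, total) counts.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    names = list(proportions)
    pct = [100.0 * p / t for p, t in proportions.values()]
    ax.bar(names, pct, color="tab:blue")
    for i, (name, (p, t)) in enumerate(proportions.items()):
        ax.text(i, pct[i], f"{p}/{t}", ha="center", va="bottom", fontsize=8)
    ax.set_ylabel("channels potentiated (%)")
    ax.tick_params(axis="x", rotation=30)
    return ax
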