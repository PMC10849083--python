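"""Simple visual summaries: proportion-over-time lines and period bar charts."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .types import SENTIMENTS


def plot_daily_proportions(
    table: pd.DataFrame, group: str, path: str | Path, boundary=None
) -> None:
    """Line chart of the seven sentiments' daily proportions for one group."""
    fig, ax = plt.subplots(figsize=(9, 4.5))
    sub = table[table["group"] == group]
    for s in SENTIMENTS:
        sel = sub[sub["sentiment"] == s].sort_values("day")
        ax.plot(sel["day"], sel["proportion"], label=s)
    if boundary is not None:
        ax.axvline(boundary, color="k", linestyle="--", linewidth=1)
    ax.set_ylabel("daily proportion")
    ax.set_title(f"sentiment proportions over time ({group} group)")
    ax.legend(ncols=4, fontsize=8)
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_period_bars(
    before: pd.DataFrame, after: pd.DataFrame, group: str, path: str | Path
) -> None:
    """Grouped bars of mean sentiment proportions before vs after the boundary."""
    fig, ax = plt.subplots(figsize=(8, 4))
    width = 0.38
    x = range(len(SENTIMENTS))
    for offset, (name, table) in ((0.0, ("before", before)), (width, ("after", after))):
        sub = table[table["group"] == group]
        means = [
            sub.loc[sub["sentiment"] == s, "proportion"].mean() for s in SENTIMENTS
        ]
        ax.bar([i + offset for i in x], means, width=width, label=name)
    ax.set_xticks([i + width / 2 for i in x])
    ax.set_xticklabels(SENTIMENTS, rotation=30)
    ax.set_ylabel("mean daily proportion")
    ax.set_title(f"{group} group, before vs after")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
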