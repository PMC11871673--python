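"""Dyad-averaged synchrony time-series plots with event markers."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .types import EventAnnotation

_COLOURS = {"HR": "#c0392b", "RMSSD": "#d4a017", "SDNN": "#27ae60"}


def plot_sync_timeseries(
    sync_df: pd.DataFrame,
    events: list[EventAnnotation],
    path: str | Path,
    *,
    delta_s: int = 5,
) -> None:
    """Plot dyad-mean dtw/second per metric over session time.

    Higher peaks mean lower synchrony.  Vertical dashed lines mark annotated
    events.  The shaded bands are +-1 standard error over dyads.
    """
    df = sync_df[sync_df["delta_s"] == delta_s].dropna(subset=["dtw_per_second"])
    fig, ax = plt.subplots(figsize=(10, 4))
    for metric, sub in df.groupby("metric"):
        g = sub.groupby("interval_start_s")["dtw_per_second"]
        mean = g.mean()
        se = g.sem()
        t = mean.index / 60.0
        colour = _COLOURS.get(metric)
        ax.plot(t, mean, label=metric, color=colour, lw=1.2)
        ax.fill_between(t, mean - se, mean + se, alpha=0.25, color=colour, lw=0)
    for i, ev in enumerate(events):
        ax.axvline(ev.t_s / 60.0, ls="--", color="grey", lw=0.8)
        ax.annotate(str(i + 1), (ev.t_s / 60.0, ax.get_ylim()[1]),
                    ha="center", va="bottom", fontsize=8)
    ax.set_xlabel("session time (min)")
    ax.set_ylabel(f"dtw per second (delta = {delta_s} s)")
    ax.legend(loc="upper right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
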