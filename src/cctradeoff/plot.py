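"""Figure helpers: extinction curves with ensemble envelopes, timelines."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_sweep_summary", "plot_timeline_summary"]

_RANK_COLOURS = {1: "#e377c2", 7: "#ff7f0e", 13: "#9edae5", 19: "#1f77b4"}


def plot_sweep_summary(summary: pd.DataFrame, x: str | None = None):
    """Mean native-extinction proportion vs the swept variable, one line
    per invader rank, shaded 95% ensemble envelope."""
    if x is None:
        x = "h" if summary["h"].nunique() > 1 else "dm"
    fig, ax = plt.subplots(figsize=(5, 4))
    for rank, sub in summary.groupby("invader_rank"):
        sub = sub.sort_values(x)
        colour = _RANK_COLOURS.get(rank)
        ax.plot(sub[x], sub["mean_extinct"], label=f"$s_{{{rank}}}$",
                color=colour)
        ax.fill_between(sub[x], sub["lo95"], sub["hi95"], alpha=0.25,
                        color=colour, linewidth=0)
    xlabel = ("invader propagule supply $h_a$" if x == "h"
              else "invader mortality reduction")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("proportion of natives extinct")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_timeline_summary(timeline: pd.DataFrame):
    """Proportion of natives extinct through time with 95% envelope."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(timeline["time"], timeline["mean_extinct"], color="#d62728")
    ax.fill_between(timeline["time"], timeline["lo95"], timeline["hi95"],
                    alpha=0.25, color="#d62728", linewidth=0)
    ax.set_xscale("log")
    ax.set_xlabel("time")
    ax.set_ylabel("proportion of natives extinct")
    fig.tight_layout()
    return fig
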