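"""Advisory plots: instantaneous-velocity traces and arrest-coefficient histograms.

Plots are diagnostic artifacts only; every quantitative result is read from
the numeric tables.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metrics import instantaneous_velocity
from .tracks import TrackSet

__all__ = ["plot_velocity_traces", "plot_arrest_histogram"]


def plot_velocity_traces(
    ts: TrackSet,
    threshold: float,
    n_tracks: int = 6,
    path=None,
):
    """Instantaneous-velocity time courses with the pause threshold dashed in red."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for tr in list(ts)[:n_tracks]:
        vs = instantaneous_velocity(tr)
        t_min = (np.arange(len(vs)) + 1) * vs.dt / 60.0
        ax.plot(t_min, vs.speeds, lw=0.9, label=f"track {tr.track_id}")
    ax.axhline(threshold, color="red", ls="--", lw=1.2, label=f"{threshold} µm/min")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("instantaneous velocity (µm/min)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_arrest_histogram(summary: pd.DataFrame, path=None, bins: int = 20):
    """Relative-frequency histogram of arrest coefficients per group."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for group, g in summary.groupby("group"):
        vals = g["arrest_coefficient"].dropna()
        ax.hist(
            vals,
            bins=bins,
            range=(0, 1),
            weights=np.full(len(vals), 1.0 / max(len(vals), 1)),
            histtype="step",
            label=f"{group} (n={len(vals)})",
        )
    ax.set_xlabel("arrest coefficient")
    ax.set_ylabel("relative frequency")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
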