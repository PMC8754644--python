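"""Quick-look figures for pipeline outputs.

Matplotlib-based convenience plots: a trajectory with its called bursts, a
population activity summary, and the autocorrelation curve against its
shuffled null.  Each function draws on a provided Axes (or a fresh one) and
returns it, statsmodels-style.
"""

from __future__ import annotations

import numpy as np

from .bursts import BurstCall, smooth
from .core import Trajectory
from .population import AutocorrResult, PopulationSeries

__all__ = ["plot_trajectory", "plot_population", "plot_autocorrelation"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_trajectory(traj: Trajectory, call: BurstCall | None = None,
                    window: int = 5, ax=None):
    """Raw and smoothed MS2 trajectory; called bursts shaded."""
    ax = _ax(ax)
    t_min = traj.time_s / 60.0
    ax.plot(t_min, traj.intensity, lw=0.8, color="0.6", label="raw")
    ax.plot(t_min, smooth(traj.intensity, window), lw=1.5, color="C0",
            label="smoothed")
    if call is not None:
        dt_min = traj.frame_interval / 60.0
        for b in call.bursts:
            ax.axvspan(b.start * dt_min, (b.end + 1) * dt_min,
                       color="C1", alpha=0.25, lw=0)
        if call.bursts:
            ax.axhline(call.threshold, color="C3", ls="--", lw=0.8,
                       label="threshold")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("MS2 intensity (AU)")
    ax.set_title(f"nucleus {traj.nucleus_id}")
    ax.legend(frameon=False, fontsize="small")
    return ax


def plot_population(pop: PopulationSeries, ax=None):
    """Instantaneous and cumulative active fractions over time."""
    ax = _ax(ax)
    t_min = pop.time_s / 60.0
    ax.plot(t_min, pop.inst_fraction, label="instantaneous", color="C0")
    ax.plot(t_min, pop.cum_fraction, label="cumulative", color="C2")
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("active fraction")
    if pop.group:
        ax.set_title(pop.group)
    ax.legend(frameon=False, fontsize="small")
    return ax


def plot_autocorrelation(res: AutocorrResult, ax=None):
    """Mean autocorrelation of the signal derivative vs the shuffled null."""
    ax = _ax(ax)
    ax.plot(res.lags_s, res.mean, color="C0", label="data")
    ax.plot(res.lags_s, res.null_mean, color="0.5", ls="--", label="shuffled")
    ax.axhline(0.0, color="0.8", lw=0.8)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("autocorrelation")
    ax.legend(frameon=False, fontsize="small")
    sd = np.std(res.curves[:, 1:], axis=0) / np.sqrt(res.curves.shape[0])
    ax.fill_between(res.lags_s[1:], res.mean[1:] - sd, res.mean[1:] + sd,
                    color="C0", alpha=0.2, lw=0)
    return ax
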