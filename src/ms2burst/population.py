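"""Group-level activity metrics, dwell-time fits, and autocorrelation.

Activity classification uses one threshold per experiment set: 10% of the
maximum MS2 intensity across all trajectories of the group.  A nucleus is
instantaneously active in a frame when its intensity exceeds the
threshold, and cumulatively active from its first such frame onward.

Periodicity is estimated from the autocorrelation of the first derivative
of the smoothed MS2 signal (the derivative removes slow trends over the
nuclear cycle).  Curves are computed on an integer-frame lag grid and
normalized to 1 at the smallest reported lag.  The null reference applies
plain autocorrelation to per-nucleus time-shuffled trajectories: a
shuffled trace is serially uncorrelated, and re-applying the smoothing
filter to it would only re-introduce the filter's own signature, so the
null is deliberately computed without it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bursts import smooth
from .core import Trajectory

__all__ = ["PopulationSeries", "ExponentialFit", "AutocorrResult",
           "active_fractions", "fit_off_durations", "autocorrelate",
           "dominant_period"]


@dataclass
class PopulationSeries:
    """Per-frame population activity of one group of nuclei."""

    frames: np.ndarray
    time_s: np.ndarray
    inst_fraction: np.ndarray     # instantaneously active / total
    cum_fraction: np.ndarray      # ever-active so far / total
    mean_active: np.ndarray       # mean intensity among active nuclei (NaN if none)
    sd_active: np.ndarray
    threshold: float
    group: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.frames, "time_s": self.time_s,
            "inst_fraction": self.inst_fraction,
            "cum_fraction": self.cum_fraction,
            "mean_active": self.mean_active, "sd_active": self.sd_active})


def active_fractions(trajectories: list[Trajectory],
                     fraction: float = 0.10,
                     threshold: float | None = None,
                     group: str = "") -> PopulationSeries:
    """Instantaneous and cumulative active fractions plus the mean MS2
    intensity per actively transcribing nucleus at each time point."""
    if not trajectories:
        raise ValueError("empty trajectory group")
    n_frames = trajectories[0].n_frames
    dt = trajectories[0].frame_interval
    mat = np.stack([t.intensity for t in trajectories])   # (N, T)
    if threshold is None:
        threshold = fraction * float(mat.max())
    active = mat > threshold
    inst = active.mean(axis=0)
    cum = np.maximum.accumulate(active, axis=1).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        masked = np.where(active, mat, np.nan)
        mean_active = np.nanmean(masked, axis=0)
        sd_active = np.nanstd(masked, axis=0)
    frames = np.arange(n_frames)
    return PopulationSeries(frames=frames, time_s=frames * dt,
                            inst_fraction=inst, cum_fraction=cum,
                            mean_active=mean_active, sd_active=sd_active,
                            threshold=float(threshold), group=group)


@dataclass(frozen=True)
class ExponentialFit:
    """Maximum-likelihood exponential fit with a KS goodness-of-fit test."""

    rate: float        # 1 / mean, in 1/min when durations are minutes
    mean: float
    n: int
    ks_statistic: float
    p_value: float


def fit_off_durations(durations: np.ndarray | list[float],
                      min_n: int = 10) -> ExponentialFit:
    """Fit a single exponential to dwell durations (ML rate = 1/mean) and
    report a Kolmogorov-Smirnov test against the fitted distribution.

    Works for OFF durations (expected to fit well when burst initiation is
    a single rate-limiting step) and equally for ON durations (where a
    poor fit indicates multi-step switch-off kinetics).
    """
    d = np.asarray(durations, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < min_n:
        raise ValueError(f"need at least {min_n} durations, got {d.size}")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    mean = float(d.mean())
    ks = stats.kstest(d, "expon", args=(0.0, mean))
    return ExponentialFit(rate=1.0 / mean, mean=mean, n=int(d.size),
                          ks_statistic=float(ks.statistic),
                          p_value=float(ks.pvalue))


@dataclass
class AutocorrResult:
    """Mean normalized autocorrelation over nuclei, with a shuffled null."""

    lags_s: np.ndarray
    mean: np.ndarray
    curves: np.ndarray            # (N_kept, n_lags)
    null_mean: np.ndarray
    shuffle_seed: int
    skipped: list[int] = field(default_factory=list)  # constant-trace nuclei

    @property
    def lags_frames(self) -> np.ndarray:
        if self.lags_s[0] == 0 and self.lags_s.size > 1:
            return np.round(self.lags_s / self.lags_s[1]).astype(int)
        return np.arange(self.lags_s.size)


def _autocov(d: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocovariance at lags 0..max_lag."""
    d = d - d.mean()
    n = d.size
    return np.array([np.dot(d[: n - k], d[k:]) / n
                     for k in range(max_lag + 1)])


def autocorrelate(trajectories: list[Trajectory],
                  frame_interval: float | None = None,
                  window: int = 5, max_lag: int | None = None,
                  normalize_lag: int = 0,
                  shuffle_seed: int = 0) -> AutocorrResult:
    """Autocorrelation of the first derivative of the smoothed MS2 signal.

    Per nucleus: smooth (5-frame boxcar) -> first difference -> biased
    sample autocorrelation on integer-frame lags -> normalize to 1 at
    ``normalize_lag`` (default: the smallest reported lag, 0).  Curves are
    averaged over nuclei.  The null curve applies plain autocorrelation to
    seeded per-nucleus time-shuffles of the raw trajectories.

    Constant traces have undefined autocorrelation and are skipped with a
    warning.
    """
    if not trajectories:
        raise ValueError("empty trajectory group")
    dt = frame_interval or trajectories[0].frame_interval
    n_frames = min(t.n_frames for t in trajectories)
    if n_frames < 2:
        raise ValueError("need at least 2 frames per trajectory")
    if max_lag is None:
        max_lag = (n_frames - 1) // 2
    rng = np.random.default_rng(shuffle_seed)

    curves, skipped = [], []
    nulls = []
    for t in trajectories:
        x = t.intensity[:n_frames]
        d = np.diff(smooth(x, window))
        c = _autocov(d, max_lag)
        if c[normalize_lag] <= 0:
            skipped.append(t.nucleus_id)
            # keep rng in lockstep so results do not depend on skips
            rng.permutation(n_frames)
            continue
        curves.append(c / c[normalize_lag])
        xs = rng.permutation(x)
        cn = _autocov(xs, max_lag)
        nulls.append(cn / cn[0] if cn[0] > 0 else np.full(max_lag + 1, np.nan))
    if skipped:
        warnings.warn(f"autocorrelation undefined for {len(skipped)} "
                      "constant trajectories; skipped")
    if not curves:
        raise ValueError("no trajectory with defined autocorrelation")
    curves_arr = np.vstack(curves)
    null_arr = np.vstack(nulls)
    lags = np.arange(normalize_lag, max_lag + 1)
    return AutocorrResult(lags_s=lags * dt,
                          mean=curves_arr.mean(axis=0)[normalize_lag:],
                          curves=curves_arr[:, normalize_lag:],
                          null_mean=np.nanmean(null_arr, axis=0)[normalize_lag:],
                          shuffle_seed=shuffle_seed,
                          skipped=skipped)


def dominant_period(result: AutocorrResult) -> float:
    """Periodicity estimate: lag (s) of the first local maximum of the mean
    curve beyond the initial anti-correlation dip.

    Falls back to the global maximum over positive lags when the curve
    never dips below zero.
    """
    c = result.mean
    lags = result.lags_s
    neg = np.nonzero(c < 0)[0]
    start = neg[0] if neg.size else 1
    if start >= c.size:
        raise ValueError("autocorrelation curve too short for a period")
    k = int(np.argmax(c[start:])) + start
    return float(lags[k])
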