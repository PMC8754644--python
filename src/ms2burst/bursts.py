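"""Burst detection and per-nucleus bursting statistics.

A burst is an episode of above-threshold activity in the smoothed
trajectory.  The calling rules, applied in a single left-to-right scan:

1. a burst opens at the first frame whose smoothed value exceeds the
   group threshold;
2. while open, the burst tracks its running local peak; it closes at the
   first frame whose value drops strictly below ``end_frac`` (default 55%)
   of that running peak — that frame is exclusive;
3. the called interval is then shifted ``shift`` frames later (default 2)
   to better center the event, clamped at the trace end;
4. bursts shorter than ``min_len`` frames (default 5) are discarded as
   detection noise;
5. a burst opening at the very first scanned frame on a monotonically
   decreasing run (a signal already decaying when observation starts) is
   discarded.

The default group threshold is 10% of the maximum smoothed intensity
across all trajectories of an experiment set, the same rule used to
classify instantaneously active nuclei; one threshold serves a whole set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory

__all__ = ["Burst", "BurstCall", "BurstStats", "smooth", "call_bursts",
           "burst_stats", "group_threshold"]


@dataclass(frozen=True)
class Burst:
    start: int            # first frame, inclusive (after shift)
    end: int              # last frame, inclusive (after shift + clamp)
    peak_value: float     # max of the smoothed trace within [start, end]
    peak_frame: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class BurstCall:
    nucleus_id: int
    bursts: list[Burst] = field(default_factory=list)
    threshold: float = 0.0

    def __post_init__(self) -> None:
        for a, b in zip(self.bursts, self.bursts[1:]):
            if b.start <= a.end:
                raise ValueError("bursts must be ordered and non-overlapping")

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)


@dataclass
class BurstStats:
    """Per-nucleus bursting parameters.

    ``amplitude`` is the mean over bursts of the smoothed-trace peak (AU);
    ``duration`` the mean burst length (s); ``total_output`` the rectangle-
    rule area under the raw trajectory over the whole analysis window
    (AU*s); ``t_first`` the onset of the first burst (s); and
    ``induction_rate`` = n_bursts / (T_end - t_first), per minute.  The
    latter two are NaN for silent nuclei.
    """

    nucleus_id: int
    n_bursts: int
    amplitude: float
    duration: float
    total_output: float
    t_first: float
    induction_rate: float
    on_durations: list[float] = field(default_factory=list)   # seconds
    off_durations: list[float] = field(default_factory=list)  # seconds


def smooth(values: np.ndarray | Trajectory, window: int = 5) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    ``smooth(x, 5)[i]`` is the mean of ``x[max(0, i-2) : i+3]``; e.g. an
    impulse ``[0, 0, 10, 0, 0]`` smooths to ``[10/3, 10/4, 2, 10/4, 10/3]``.
    """
    if isinstance(values, Trajectory):
        values = values.intensity
    x = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > x.size:
        raise ValueError("window longer than the trace")
    if window == 1:
        return x.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def group_threshold(trajectories: list[Trajectory] | list[np.ndarray],
                    fraction: float = 0.10, window: int = 5,
                    override: float | None = None) -> float:
    """Burst-start threshold for one experiment set.

    Default: ``fraction`` (10%) of the maximum smoothed intensity across
    all trajectories of the group.  A config ``override`` wins when given.
    """
    if override is not None:
        return float(override)
    if not trajectories:
        raise ValueError("empty trajectory group")
    gmax = max(float(np.max(smooth(t, window))) for t in trajectories)
    if gmax <= 0:
        raise ValueError("all-zero trajectory group: threshold undefined")
    return fraction * gmax


def _strictly_decreasing(x: np.ndarray) -> bool:
    return x.size >= 2 and bool(np.all(np.diff(x) < 0))


def call_bursts(smoothed: np.ndarray, threshold: float, min_len: int = 5,
                end_frac: float = 0.55, shift: int = 2,
                nucleus_id: int = 0) -> BurstCall:
    """Detect bursts in a smoothed trajectory.  See the module docstring
    for the rules.  Silent traces return an empty call, never an error.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    s = np.asarray(smoothed, dtype=float)
    n = s.size
    raw_intervals: list[tuple[int, int]] = []  # [start, end_exclusive) pre-shift
    i = 0
    while i < n:
        if s[i] <= threshold:
            i += 1
            continue
        start = i
        peak = s[i]
        j = i + 1
        end_ex = n
        while j < n:
            if s[j] < end_frac * peak:
                end_ex = j
                break
            peak = max(peak, s[j])
            j += 1
        raw_intervals.append((start, end_ex))
        # detection resumes at the closing frame, which may itself open the
        # next burst if it is still above the group threshold
        i = end_ex

    bursts: list[Burst] = []
    for start, end_ex in raw_intervals:
        # initial-decline rule: a trace already decaying at the start of
        # detection is not a burst
        if start == 0 and _strictly_decreasing(s[:min(min_len, n)]):
            continue
        new_start = start + shift
        new_end = min(end_ex - 1 + shift, n - 1)
        if new_start > n - 1:
            continue  # pushed entirely off the end
        if new_end - new_start + 1 < min_len:
            continue  # false positive from detection noise
        if bursts and new_start <= bursts[-1].end:
            # merge on overlap (can only arise from end-clamping)
            prev = bursts.pop()
            new_start = prev.start
        seg = s[new_start:new_end + 1]
        pk = int(np.argmax(seg))
        bursts.append(Burst(start=new_start, end=new_end,
                            peak_value=float(seg[pk]),
                            peak_frame=new_start + pk))
    return BurstCall(nucleus_id=nucleus_id, bursts=bursts,
                     threshold=float(threshold))


def burst_stats(call: BurstCall, raw: Trajectory,
                smoothed: np.ndarray | None = None,
                window: int = 5) -> BurstStats:
    """Per-nucleus bursting parameters from a call and its trajectory.

    ``total_output`` integrates the full raw trace (rectangle rule), not
    only in-burst frames; excluded frames contribute zero.
    """
    dt = raw.frame_interval
    if smoothed is None:
        smoothed = smooth(raw.intensity, window)
    valid = raw.valid_mask()
    total_output = float(np.sum(raw.intensity[valid]) * dt)
    n = call.n_bursts
    if n == 0:
        return BurstStats(nucleus_id=call.nucleus_id, n_bursts=0,
                          amplitude=float("nan"), duration=float("nan"),
                          total_output=total_output, t_first=float("nan"),
                          induction_rate=float("nan"))
    amp = float(np.mean([np.max(smoothed[b.start:b.end + 1])
                         for b in call.bursts]))
    on = [b.length * dt for b in call.bursts]
    off = [(b.start - a.end - 1) * dt
           for a, b in zip(call.bursts, call.bursts[1:])]
    t_first = call.bursts[0].start * dt
    t_end = (raw.n_frames - 1) * dt
    span = t_end - t_first
    rate = float("nan") if span <= 0 else n / span * 60.0  # per minute
    return BurstStats(nucleus_id=call.nucleus_id, n_bursts=n,
                      amplitude=amp, duration=float(np.mean(on)),
                      total_output=total_output, t_first=t_first,
                      induction_rate=rate, on_durations=on,
                      off_durations=off)
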