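"""Ground-truthed synthetic MS2/MCP data.

This module emulates the statistical structure of nuclear-cycle-14
live-imaging data so that every downstream stage of the pipeline can be
verified without the original movies:

* per-nucleus MS2 trajectories from a two-state (telegraph) promoter —
  exact continuous-time switching with exponential dwell times, Poisson
  Pol II loading while ON, and a boxcar nascent-transcript kernel (each
  transcript contributes ``unit_intensity`` for exactly ``dwell`` minutes);
* rendered two-channel movies: a histone-like channel of drifting textured
  disks and an MS2 channel of diffraction-limited Gaussian dots whose
  integrated intensity equals the true trajectory value;
* striped anterior-posterior expression fields for the spatial
  reconstitution stage.

The ON-exit can optionally proceed through several sequential exponential
stages (``off_steps`` > 1), producing Erlang-distributed ON durations — a
multi-step OFF-switch — while OFF durations stay single-exponential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Track, Trajectory

__all__ = [
    "TelegraphParams", "FieldParams", "GroundTruth",
    "simulate_trajectory", "simulate_periodic_trajectory",
    "render_movie", "variant_presets", "VARIANT_PRESETS",
]


@dataclass(frozen=True)
class TelegraphParams:
    """Kinetic and sampling parameters of one simulated promoter.

    Rates are per minute, durations in minutes, ``frame_interval`` in
    seconds.  ``unit_intensity`` is the fluorescence contribution of a
    single nascent transcript (AU); ``noise_sd`` an additive Gaussian
    noise scale applied to the sampled trace (AU).
    """

    k_on: float = 0.5          # OFF -> ON rate (1/min)
    k_off: float = 0.7         # ON -> OFF rate (1/min)
    r_load: float = 20.0       # Pol II initiations per minute while ON
    dwell: float = 1.5         # residence time of one transcript's signal (min)
    unit_intensity: float = 200.0
    noise_sd: float = 0.0
    onset_delay: float = 0.0   # minutes before the promoter may first activate
    frame_interval: float = 16.8  # seconds per frame
    n_frames: int = 180
    off_steps: int = 1         # >1 = Erlang ON durations (multi-step switch-off)

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "r_load", "dwell", "unit_intensity",
                     "noise_sd", "onset_delay", "frame_interval"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.off_steps < 1:
            raise ValueError("off_steps must be >= 1")

    @property
    def total_minutes(self) -> float:
        return self.n_frames * self.frame_interval / 60.0

    @property
    def frame_times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval / 60.0


@dataclass(frozen=True)
class FieldParams:
    """Geometry of a rendered embryo field.

    ``stripe_pattern`` optionally assigns promoter kinetics by horizontal
    position: a list of ``((x_lo, x_hi), TelegraphParams)`` with bounds as
    fractions of image width.  Nuclei outside every stripe are silent.
    """

    image_shape: tuple[int, int] = (400, 400)
    n_z: int = 3
    n_nuclei: int = 100
    nucleus_radius: float = 9.0
    drift_sd: float = 0.3        # px per frame
    psf_sigma: float = 1.5       # px, MS2 dot spread
    min_gap: float = 4.0         # px clearance between nucleus rims
    histone_level: float = 6000.0
    histone_bg: float = 400.0
    ms2_bg: float = 100.0
    noise_sd: float = 0.0        # per-pixel Gaussian image noise (both channels)
    stripe_pattern: list[tuple[tuple[float, float], TelegraphParams]] | None = None

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be > 0")
        if self.drift_sd >= self.nucleus_radius:
            raise ValueError("drift_sd must be smaller than nucleus_radius")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")


@dataclass
class GroundTruth:
    """Everything the renderer knows, for verifying the pipeline.

    masks : (T, Y, X) uint16 — per-frame label rasters, label = nucleus id.
    tracks : list of Track — true lineages.
    trajectories : list of Trajectory — noiseless per-nucleus signal.
    bursts : DataFrame (nucleus_id, t_start_s, t_end_s) — true ON intervals.
    spot_centers : (N, T, 3) float — (z, y, x) dot position per frame.
    """

    masks: np.ndarray
    tracks: list[Track]
    trajectories: list[Trajectory]
    bursts: pd.DataFrame
    spot_centers: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.tracks)
        t = self.masks.shape[0]
        if len(self.trajectories) != n:
            raise ValueError("tracks and trajectories disagree on nucleus count")
        for tr in self.trajectories:
            if tr.n_frames != t:
                raise ValueError("trajectory length does not match mask count")


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _simulate_switching(params: TelegraphParams,
                        rng: np.random.Generator
                        ) -> tuple[list[tuple[float, float]], np.ndarray]:
    """Event-driven two-state switching; returns ON intervals (min, clipped
    to the trace) and sorted Pol II initiation times (min)."""
    T = params.total_minutes
    on_intervals: list[tuple[float, float]] = []
    inits: list[np.ndarray] = []
    t = params.onset_delay
    if params.k_on > 0:
        while t < T:
            t = t + rng.exponential(1.0 / params.k_on)
            if t >= T:
                break
            if params.k_off > 0:
                # Erlang(off_steps) exit keeps the mean ON duration 1/k_off
                dur = float(rng.exponential(
                    1.0 / (params.off_steps * params.k_off),
                    size=params.off_steps).sum())
            else:
                dur = math.inf
            t_end = min(t + dur, T)
            on_intervals.append((t, t_end))
            if params.r_load > 0:
                n = rng.poisson(params.r_load * (t_end - t))
                if n:
                    inits.append(rng.uniform(t, t_end, n))
            t = t + dur
    init_times = (np.sort(np.concatenate(inits)) if inits
                  else np.empty(0, dtype=float))
    return on_intervals, init_times


def _sample_signal(params: TelegraphParams, init_times: np.ndarray
                   ) -> np.ndarray:
    """Noiseless fluorescence per frame under the boxcar dwell kernel."""
    ft = params.frame_times_min
    hi = np.searchsorted(init_times, ft, side="right")
    lo = np.searchsorted(init_times, ft - params.dwell, side="right")
    return params.unit_intensity * (hi - lo).astype(float)


def simulate_trajectory(params: TelegraphParams, seed: int | np.random.Generator
                        ) -> tuple[Trajectory, list[tuple[float, float]]]:
    """Simulate one telegraph-promoter MS2 trajectory.

    Returns the sampled trajectory (AU per frame, Gaussian noise added and
    clipped at zero) and the list of true ON intervals in seconds.
    Bit-reproducible for a fixed integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    on_intervals, init_times = _simulate_switching(params, rng)
    signal = _sample_signal(params, init_times)
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, params.n_frames)
    signal = np.clip(signal, 0.0, None)
    traj = Trajectory(nucleus_id=0, intensity=signal,
                      frame_interval=params.frame_interval)
    return traj, [(a * 60.0, b * 60.0) for a, b in on_intervals]


def simulate_periodic_trajectory(period_frames: int, duty: float,
                                 level: float, n_frames: int,
                                 frame_interval: float = 16.8,
                                 noise_sd: float = 0.0,
                                 seed: int | np.random.Generator = 0
                                 ) -> Trajectory:
    """Deterministically periodic bursting (square wave) with a random phase.

    Useful for validating periodicity estimation: the trace is ON at
    ``level`` for ``duty * period_frames`` frames out of every period.
    """
    if not 0 < duty < 1:
        raise ValueError("duty must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    phase = rng.integers(0, period_frames)
    f = (np.arange(n_frames) + phase) % period_frames
    sig = np.where(f < duty * period_frames, float(level), 0.0)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, n_frames)
    return Trajectory(nucleus_id=0, intensity=np.clip(sig, 0.0, None),
                      frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# field rendering
# ---------------------------------------------------------------------------

def _place_nuclei(fp: FieldParams, rng: np.random.Generator) -> np.ndarray:
    """Random sequential placement of non-overlapping disks; (N, 2) (y, x)."""
    h, w = fp.image_shape
    r = fp.nucleus_radius
    margin = r + 2.0
    min_d2 = (2.0 * r + fp.min_gap) ** 2
    centers: list[tuple[float, float]] = []
    for _ in range(fp.n_nuclei):
        for attempt in range(1000):
            y = rng.uniform(margin, h - margin)
            x = rng.uniform(margin, w - margin)
            if all((y - cy) ** 2 + (x - cx) ** 2 >= min_d2
                   for cy, cx in centers):
                centers.append((y, x))
                break
        else:
            raise RuntimeError(
                f"could not place nucleus {len(centers) + 1}/{fp.n_nuclei} "
                "without overlap after 1000 attempts; reduce n_nuclei or "
                "nucleus_radius")
    return np.asarray(centers)


def _params_for_position(fp: FieldParams, x: float,
                         default: TelegraphParams | None
                         ) -> TelegraphParams | None:
    if fp.stripe_pattern is None:
        return default
    frac = x / fp.image_shape[1]
    for (lo, hi), p in fp.stripe_pattern:
        if lo <= frac < hi:
            return p
    return None  # outside every stripe: silent


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, r: float
               ) -> tuple[np.ndarray, np.ndarray]:
    y0, y1 = int(max(0, cy - r - 1)), int(min(shape[0], cy + r + 2))
    x0, x1 = int(max(0, cx - r - 1)), int(min(shape[1], cx + r + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return yy[inside], xx[inside]


def render_movie(field: FieldParams,
                 params: TelegraphParams | list[TelegraphParams] | None = None,
                 seed: int = 0,
                 n_frames: int | None = None
                 ) -> tuple[np.ndarray, GroundTruth]:
    """Render a two-channel synthetic movie with full ground truth.

    Parameters
    ----------
    field : FieldParams
    params : TelegraphParams, list of them (one per nucleus), or None
        Promoter kinetics.  Ignored for nuclei governed by
        ``field.stripe_pattern``; required otherwise.
    seed : int
        Master seed; placement, drift, kinetics and noise all derive from it.
    n_frames : int, optional
        Overrides the frame count of ``params`` (all per-nucleus parameter
        sets must agree on n_frames and frame_interval).

    Returns
    -------
    movie : (T, Z, C, Y, X) uint16 — channel 0 histone, channel 1 MS2.
    truth : GroundTruth
    """
    rng = np.random.default_rng(seed)
    h, w = field.image_shape
    centers0 = _place_nuclei(field, rng)
    n = field.n_nuclei

    # resolve per-nucleus kinetics
    if isinstance(params, TelegraphParams):
        per_nucleus: list[TelegraphParams | None] = [params] * n
    elif params is None:
        per_nucleus = [None] * n
    else:
        if len(params) != n:
            raise ValueError("need one TelegraphParams per nucleus")
        per_nucleus = list(params)
    per_nucleus = [_params_for_position(field, c[1], p)
                   for c, p in zip(centers0, per_nucleus)]
    ref = next((p for p in per_nucleus if p is not None), None)
    if ref is None and field.stripe_pattern is None and params is None:
        raise ValueError("no promoter parameters supplied")
    if ref is None:
        ref = TelegraphParams()  # all-silent field: only sampling grid needed
    T = int(n_frames if n_frames is not None else ref.n_frames)
    dt = ref.frame_interval

    # per-nucleus true signal
    trajectories: list[Trajectory] = []
    burst_rows = []
    child = rng.spawn(n)
    for i, p in enumerate(per_nucleus):
        if p is None:
            sig = np.zeros(T)
            intervals: list[tuple[float, float]] = []
        else:
            p = replace(p, n_frames=T, frame_interval=dt, noise_sd=0.0)
            tr, intervals = simulate_trajectory(p, child[i])
            sig = tr.intensity
        trajectories.append(Trajectory(nucleus_id=i + 1, intensity=sig,
                                       frame_interval=dt))
        for a, b in intervals:
            burst_rows.append((i + 1, a, b))
    bursts = pd.DataFrame(burst_rows,
                          columns=["nucleus_id", "t_start_s", "t_end_s"])

    # drift: Gaussian steps, clamped so disks stay inside the frame and
    # rejected (nucleus stays put) when a step would bring two nuclei into
    # contact — interphase nuclei exclude one another
    r = field.nucleus_radius
    margin = r + 2.0
    min_d2 = (2.0 * r + 0.5 * field.min_gap) ** 2
    centers = np.empty((T, n, 2))
    centers[0] = centers0
    for t in range(1, T):
        prev = centers[t - 1]
        if field.drift_sd > 0:
            c = prev + rng.normal(0.0, field.drift_sd, (n, 2))
        else:
            c = prev.copy()
        c[:, 0] = np.clip(c[:, 0], margin, h - margin)
        c[:, 1] = np.clip(c[:, 1], margin, w - margin)
        for _ in range(5):
            d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            bad = np.unique(np.nonzero(d2 < min_d2)[0])
            if bad.size == 0:
                break
            c[bad] = prev[bad]
        centers[t] = c

    # static per-nucleus appearance details
    dot_off = rng.uniform(-r / 3.0, r / 3.0, (n, 2))
    dot_z = rng.integers(0, field.n_z, n)
    chromo_off = rng.uniform(-r / 2.5, r / 2.5, (n, 2))
    texture_gain = rng.uniform(0.9, 1.1, n)
    sigma_z = 0.8  # planes; attenuation of the dot away from its home plane

    movie = np.zeros((T, field.n_z, 2, h, w), dtype=np.uint16)
    masks = np.zeros((T, h, w), dtype=np.uint16)
    spot_centers = np.empty((n, T, 3))
    amp_norm = 2.0 * math.pi * field.psf_sigma ** 2

    for t in range(T):
        his = np.full((h, w), field.histone_bg, dtype=float)
        ms2 = np.full((h, w), field.ms2_bg, dtype=float)
        for i in range(n):
            cy, cx = centers[t, i]
            yy, xx = _disk_mask((h, w), cy, cx, r)
            masks[t, yy, xx] = i + 1
            # textured disk + a small bright chromocenter-like speckle
            rad2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (r * r)
            his[yy, xx] = field.histone_level * texture_gain[i] * \
                (1.0 - 0.25 * rad2)
            sy = int(round(cy + chromo_off[i, 0]))
            sx = int(round(cx + chromo_off[i, 1]))
            his[max(0, sy - 1):sy + 1, max(0, sx - 1):sx + 1] = \
                min(2.2 * field.histone_level, 60000.0)
            spot_centers[i, t] = (dot_z[i], cy + dot_off[i, 0],
                                  cx + dot_off[i, 1])
        if field.noise_sd > 0:
            his = his + rng.normal(0.0, field.noise_sd, (h, w))
        his_u16 = np.clip(np.round(his), 0, 65535).astype(np.uint16)

        for z in range(field.n_z):
            movie[t, z, 0] = his_u16
            plane = ms2.copy()
            for i in range(n):
                v = trajectories[i].intensity[t]
                if v <= 0:
                    continue
                zf = math.exp(-0.5 * ((z - dot_z[i]) / sigma_z) ** 2)
                if zf < 1e-4:
                    continue
                dy, dx = spot_centers[i, t, 1], spot_centers[i, t, 2]
                s = field.psf_sigma
                ylo, yhi = int(max(0, dy - 6 * s)), int(min(h, dy + 6 * s + 1))
                xlo, xhi = int(max(0, dx - 6 * s)), int(min(w, dx + 6 * s + 1))
                gy = np.arange(ylo, yhi) - dy
                gx = np.arange(xlo, xhi) - dx
                g = np.exp(-0.5 * (gy[:, None] ** 2 + gx[None, :] ** 2) / s ** 2)
                plane[ylo:yhi, xlo:xhi] += v * zf / amp_norm * g
            if field.noise_sd > 0:
                plane = plane + rng.normal(0.0, field.noise_sd, (h, w))
            movie[t, z, 1] = np.clip(np.round(plane), 0, 65535).astype(np.uint16)

    tracks = []
    for i in range(n):
        tr = Track(nucleus_id=i + 1)
        for t in range(T):
            tr.append(t, i + 1, tuple(centers[t, i]))
        tracks.append(tr)

    truth = GroundTruth(masks=masks, tracks=tracks, trajectories=trajectories,
                        bursts=bursts, spot_centers=spot_centers)
    return movie, truth


# ---------------------------------------------------------------------------
# promoter-variant presets
# ---------------------------------------------------------------------------

#: Ordinal relations encoded by construction (absolute values are package
#: choices, not measurements): the TATA mutant lowers both loading rate
#: (amplitude) and activation rate (frequency); Inr/MTE/DPE mutants lower the
#: activation rate and delay the first activation, with DPE/Inr hit harder
#: than MTE; extra Zelda sites shorten the onset delay.
VARIANT_PRESETS: dict[str, TelegraphParams] = {
    "WT":    TelegraphParams(k_on=0.50, k_off=0.70, r_load=20.0, dwell=1.5,
                             onset_delay=3.0, noise_sd=150.0),
    "mTATA": TelegraphParams(k_on=0.30, k_off=0.70, r_load=10.0, dwell=1.5,
                             onset_delay=4.0, noise_sd=150.0),
    "mInr":  TelegraphParams(k_on=0.15, k_off=0.70, r_load=16.0, dwell=1.5,
                             onset_delay=8.0, noise_sd=150.0),
    "mMTE":  TelegraphParams(k_on=0.30, k_off=0.70, r_load=18.0, dwell=1.5,
                             onset_delay=6.0, noise_sd=150.0),
    "mDPE":  TelegraphParams(k_on=0.12, k_off=0.70, r_load=16.0, dwell=1.5,
                             onset_delay=8.0, noise_sd=150.0),
    "Zelda": TelegraphParams(k_on=0.60, k_off=0.70, r_load=20.0, dwell=1.5,
                             onset_delay=1.0, noise_sd=150.0),
}


def variant_presets(name: str) -> TelegraphParams:
    """Telegraph parameters mimicking one of the promoter variants.

    Only the ordinal relations between presets (e.g. WT amplitude >
    mTATA amplitude, Zelda onset < WT onset) are meaningful.
    """
    try:
        return VARIANT_PRESETS[name]
    except KeyError:
        valid = ", ".join(sorted(VARIANT_PRESETS))
        raise KeyError(f"unknown variant {name!r}; valid presets: {valid}") \
            from None
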