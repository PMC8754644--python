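"""MS2 spot localization, 2-D Gaussian fitting, and trajectory extraction.

The transcription site of a nucleus is the brightest voxel of the raw 3-D
MS2 stack among voxels whose projected (y, x) position falls inside the
nucleus's segmented region.  A 2-D Gaussian

    I(x, y) = alpha + I0 * exp(-((x - x0)^2 / (2 sx^2)
                                 + (y - y0)^2 / (2 sy^2)))

is fitted by nonlinear least squares in an 11 x 11 window at the spot's
z-plane; the background-subtracted spot intensity is the closed-form
integral ``2 pi sx sy I0``.  Fits whose extent exceeds the window
(2 sigma > window/2 on either axis) or that fail to converge are invalid:
the whole time point of that nucleus is excluded from totals, with the
value linearly interpolated so that smoothing stays defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import LabelMask, Track, Trajectory

__all__ = ["SpotFit", "locate_spot", "fit_spot", "spot_invalidation",
           "baseline_correct", "extract_trajectories"]

SIGMA_MIN, SIGMA_MAX = 0.3, 8.0  # px; numerical-stability bounds on the fit


@dataclass(frozen=True)
class SpotFit:
    """Result of one 2-D Gaussian spot fit (coordinates in full-image px)."""

    alpha: float          # local background (AU)
    I0: float             # peak amplitude above background (AU)
    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    residual: float       # RMS of the fit residual
    valid: bool
    clipped: bool = False  # window clipped at an image edge
    z: int | None = None

    @property
    def integral(self) -> float:
        """Background-subtracted spot intensity, ``2 pi sx sy I0``.

        NaN for invalid fits (they carry no integral).
        """
        if not self.valid:
            return float("nan")
        return 2.0 * math.pi * self.sigma_x * self.sigma_y * self.I0


def locate_spot(volume: np.ndarray, mask: np.ndarray | LabelMask,
                label: int) -> tuple[int, int, int]:
    """Brightest voxel of ``volume`` (Z, Y, X) within a nucleus footprint.

    All z-planes above the label's projected (y, x) region are searched;
    ties are broken by lowest z, then row-major (y, x) order.
    """
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    ys, xs = np.nonzero(labels == label)
    if ys.size == 0:
        raise ValueError(f"label {label} not present in mask")
    sub = volume[:, ys, xs]                      # (Z, n_pixels)
    flat = int(np.argmax(sub))                   # first max in C order:
    z, k = divmod(flat, ys.size)                 # lowest z, then row-major
    return int(z), int(ys[k]), int(xs[k])


def _gauss2d(coords, alpha, I0, x0, y0, sx, sy):
    y, x = coords
    return alpha + I0 * np.exp(-((x - x0) ** 2 / (2.0 * sx ** 2)
                                 + (y - y0) ** 2 / (2.0 * sy ** 2)))


def _gauss2d_jac(coords, alpha, I0, x0, y0, sx, sy):
    y, x = coords
    dx, dy = x - x0, y - y0
    e = np.exp(-(dx ** 2 / (2.0 * sx ** 2) + dy ** 2 / (2.0 * sy ** 2)))
    return np.stack([np.ones_like(e), e,
                     I0 * e * dx / sx ** 2, I0 * e * dy / sy ** 2,
                     I0 * e * dx ** 2 / sx ** 3,
                     I0 * e * dy ** 2 / sy ** 3], axis=1)


def fit_spot(plane: np.ndarray, center: tuple[int, int], window: int = 11,
             pixel_mask: np.ndarray | None = None) -> SpotFit:
    """Fit the 2-D Gaussian in a ``window`` x ``window`` region around
    ``center`` (y, x).  Near an image edge the window is clipped and the
    fit flagged.  ``pixel_mask`` (same shape as ``plane``, True = usable)
    restricts the fit to pixels assigned to the nucleus under analysis, so
    a neighboring nucleus's dot entering the window cannot contaminate the
    fit.  Solver failure yields ``valid=False``, never an exception.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    half = window // 2
    cy, cx = int(center[0]), int(center[1])
    h, w = plane.shape
    y0w, y1w = max(0, cy - half), min(h, cy + half + 1)
    x0w, x1w = max(0, cx - half), min(w, cx + half + 1)
    clipped = (y1w - y0w != window) or (x1w - x0w != window)
    region = np.asarray(plane[y0w:y1w, x0w:x1w], dtype=float)
    yy, xx = np.mgrid[y0w:y1w, x0w:x1w]

    border = np.concatenate([region[0, :], region[-1, :],
                             region[1:-1, 0], region[1:-1, -1]])
    alpha0 = float(np.median(border))
    I0_init = max(float(plane[cy, cx]) - alpha0, 0.0)

    if pixel_mask is not None:
        keep = np.asarray(pixel_mask, dtype=bool)
        if keep.shape == plane.shape:
            keep = keep[y0w:y1w, x0w:x1w]
        elif keep.shape != region.shape:
            raise ValueError("pixel_mask must match the plane or the window")
        if keep.sum() >= 12:   # enough pixels to constrain 6 parameters
            region = region[keep]
            yy, xx = yy[keep], xx[keep]
    p0 = [alpha0, I0_init, float(cx), float(cy), 1.5, 1.5]
    # the dot was located at the brightest pixel, so its fitted center may
    # not wander far from it: keeps the fit from latching onto structure
    # (e.g. a neighboring nucleus's dot) entering the window edge
    wiggle = window / 4.0
    lower = [-np.inf, 0.0, cx - wiggle, cy - wiggle, SIGMA_MIN, SIGMA_MIN]
    upper = [np.inf, np.inf, cx + wiggle, cy + wiggle, SIGMA_MAX, SIGMA_MAX]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # well-posed dot fits converge in well under 100 evaluations;
            # the cap cuts off hopeless fits on dotless noise quickly (they
            # end invalid either way)
            popt, _ = curve_fit(_gauss2d, (yy.ravel(), xx.ravel()),
                                region.ravel(), p0=p0, jac=_gauss2d_jac,
                                bounds=(lower, upper), maxfev=400)
    except (RuntimeError, ValueError):
        return SpotFit(alpha=float("nan"), I0=float("nan"), x0=float("nan"),
                       y0=float("nan"), sigma_x=float("nan"),
                       sigma_y=float("nan"), residual=float("nan"),
                       valid=False, clipped=clipped)
    alpha, I0, x0, y0, sx, sy = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean(
        (region.ravel() - _gauss2d((yy.ravel(), xx.ravel()), *popt)) ** 2)))
    # "larger than the fitted region": dot extent exceeds the half-window
    too_big = (2.0 * sx > window / 2.0) or (2.0 * sy > window / 2.0)
    return SpotFit(alpha=alpha, I0=I0, x0=x0, y0=y0, sigma_x=sx, sigma_y=sy,
                   residual=resid, valid=not too_big, clipped=clipped)


def spot_invalidation(fit: SpotFit, nucleus_id: int, frame: int
                      ) -> tuple[int, int] | None:
    """Exclusion record ``(nucleus_id, frame)`` for an invalid fit.

    Valid fits yield ``None``.  Excluded frames are interpolated for
    smoothing downstream but never contribute to output totals.
    """
    return None if fit.valid else (int(nucleus_id), int(frame))


def baseline_correct(traj: Trajectory) -> Trajectory:
    """Subtract the per-trajectory minimum so the baseline sits at zero.

    The minimum is taken over non-excluded frames; the result is
    non-negative there by construction.
    """
    valid = traj.valid_mask()
    if not valid.any():
        raise ValueError("cannot baseline-correct an all-excluded trajectory")
    vals = traj.intensity[valid]
    if not np.isfinite(vals).any():
        raise ValueError("trajectory has no finite values")
    base = float(np.nanmin(vals))
    out = np.clip(traj.intensity - base, 0.0, None)
    return traj.replace(intensity=out, baseline_corrected=True)


def _interpolate_excluded(values: np.ndarray, excluded: set[int]
                          ) -> np.ndarray:
    if not excluded:
        return values
    out = values.copy()
    n = out.size
    good = np.array([i for i in range(n) if i not in excluded])
    bad = np.array(sorted(excluded))
    if good.size == 0:
        out[:] = 0.0
        return out
    out[bad] = np.interp(bad, good, out[good])
    return out


def extract_trajectories(ms2_volume: np.ndarray,
                         masks: list[LabelMask] | np.ndarray,
                         tracks: list[Track],
                         frame_interval: float,
                         window: int = 11,
                         baseline: bool = True
                         ) -> tuple[list[Trajectory], pd.DataFrame]:
    """Per-nucleus MS2 trajectories from the raw 3-D MS2 channel.

    Parameters
    ----------
    ms2_volume : (T, Z, Y, X) array — raw MS2 stacks.
    masks : per-frame label masks (list or (T, Y, X) array).
    tracks : linked lineages; each yields one trajectory over the frames it
        covers (values at uncovered/gap frames are interpolated and flagged
        excluded).
    frame_interval : seconds per frame.
    baseline : subtract the per-trajectory minimum (default True).

    Returns the trajectories and a tidy DataFrame of every spot fit.
    """
    if isinstance(masks, np.ndarray):
        label_frames = [masks[t] for t in range(masks.shape[0])]
    else:
        label_frames = [m.labels for m in masks]
    T = ms2_volume.shape[0]

    # per-frame centroid tables for nearest-region pixel ownership: window
    # pixels inside another nucleus, or background nearer to another
    # nucleus's centroid, are excluded from the fit
    frame_cents: list[dict[int, tuple[float, float]]] = [{} for _ in range(T)]
    for tr in tracks:
        for f, lab, c in zip(tr.frames, tr.labels, tr.centroids):
            frame_cents[f][lab] = c

    half = window // 2

    def _ownership(f: int, lab: int, y: int, x: int) -> np.ndarray:
        L = label_frames[f]
        h, w = L.shape
        sl = (slice(max(0, y - half), min(h, y + half + 1)),
              slice(max(0, x - half), min(w, x + half + 1)))
        Lw = L[sl]
        own = Lw == lab
        bg = Lw == 0
        if bg.any() and len(frame_cents[f]) > 1:
            labs = np.fromiter(frame_cents[f], dtype=int)
            cents = np.asarray([frame_cents[f][k] for k in labs])
            by, bx = np.nonzero(bg)
            py = by + sl[0].start
            px = bx + sl[1].start
            d2 = (cents[:, 0][:, None] - py) ** 2 \
                + (cents[:, 1][:, None] - px) ** 2
            nearest = labs[np.argmin(d2, axis=0)]
            own[by, bx] = nearest == lab
        else:
            own |= bg
        return own

    trajs: list[Trajectory] = []
    fit_rows = []
    for tr in tracks:
        values = np.zeros(T)
        excluded: set[int] = set(range(T))
        by_frame = tr.to_frame_dict()
        for f, (lab, _c) in by_frame.items():
            try:
                z, y, x = locate_spot(ms2_volume[f], label_frames[f], lab)
            except ValueError:
                continue
            fit = fit_spot(ms2_volume[f, z], (y, x), window=window,
                           pixel_mask=_ownership(f, lab, y, x))
            fit_rows.append((tr.nucleus_id, f, z, fit.alpha, fit.I0, fit.x0,
                             fit.y0, fit.sigma_x, fit.sigma_y, fit.integral,
                             fit.residual, fit.valid, fit.clipped))
            if fit.valid:
                values[f] = fit.integral
                excluded.discard(f)
        values = _interpolate_excluded(values, excluded)
        traj = Trajectory(nucleus_id=tr.nucleus_id, intensity=values,
                          frame_interval=frame_interval,
                          excluded=frozenset(excluded))
        if baseline and len(excluded) < T:
            traj = baseline_correct(traj)
        trajs.append(traj)
    fits = pd.DataFrame(fit_rows, columns=[
        "nucleus_id", "frame", "z", "alpha", "I0", "x0", "y0",
        "sigma_x", "sigma_y", "integral", "residual", "valid", "clipped"])
    return trajs, fits
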