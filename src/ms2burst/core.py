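"""Shared data containers for the bursting-analysis pipeline.

Conventions used throughout the package:

* rasters are indexed ``(row=y, col=x)``, 0-based;
* label masks are 16-bit integer images with 0 = background and each
  nucleus a positive label;
* times attached to trajectories are in seconds (``time_s = frame *
  frame_interval``); kinetic rates are quoted per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabelMask", "Track", "Trajectory"]


@dataclass
class LabelMask:
    """A single frame of segmented nuclei.

    Attributes
    ----------
    frame : int
        Frame index within the movie.
    labels : ndarray of uint16, shape (Y, X)
        0 = background, k > 0 = nucleus k.
    method : str
        Provenance tag: ``"method-1"``, ``"method-2"``, ``"override"``
        or ``"ground-truth"``.
    threshold : float or None
        Binarization threshold that produced the mask, when applicable.
    """

    frame: int
    labels: np.ndarray
    method: str = "method-1"
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative integers")

    @property
    def n_labels(self) -> int:
        return int(np.count_nonzero(np.unique(self.labels)))

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class Track:
    """Time-linked lineage of one nucleus.

    ``frames`` are strictly increasing; ``labels[i]`` is the mask label of
    this nucleus at ``frames[i]`` and ``centroids[i]`` its (y, x) centroid.
    Frames missing from ``frames`` (short gaps tolerated by the linker) are
    gaps; ``gap_flags`` marks entries that immediately follow a gap.
    """

    nucleus_id: int
    frames: list[int] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    gap_flags: list[bool] = field(default_factory=list)

    def append(self, frame: int, label: int, centroid: tuple[float, float],
               gap: bool = False) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("track frames must be strictly increasing")
        self.frames.append(int(frame))
        self.labels.append(int(label))
        self.centroids.append((float(centroid[0]), float(centroid[1])))
        self.gap_flags.append(bool(gap))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start_frame(self) -> int:
        return self.frames[0]

    @property
    def end_frame(self) -> int:
        return self.frames[-1]

    def to_frame_dict(self) -> dict[int, tuple[int, tuple[float, float]]]:
        return {f: (l, c) for f, l, c in
                zip(self.frames, self.labels, self.centroids)}


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for f, lab, (cy, cx), g in zip(tr.frames, tr.labels, tr.centroids,
                                       tr.gap_flags):
            rows.append((tr.nucleus_id, f, lab, cy, cx, g))
    return pd.DataFrame(rows, columns=["nucleus_id", "frame", "label",
                                       "y", "x", "gap"])


@dataclass
class Trajectory:
    """Per-nucleus time series of MS2 spot intensity.

    ``intensity`` is in arbitrary fluorescence units (the background-
    subtracted 2-D Gaussian integral for measured data, or the noiseless
    nascent-transcript signal for simulated ground truth).  Frames whose
    spot fit was rejected are listed in ``excluded`` and carry linearly
    interpolated values so that smoothing stays well defined; downstream
    totals must honour the flag.
    """

    nucleus_id: int
    intensity: np.ndarray
    frame_interval: float  # seconds
    frames: np.ndarray | None = None
    excluded: frozenset[int] = frozenset()
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise ValueError("trajectory intensity must be 1-D")
        if self.frames is None:
            self.frames = np.arange(self.intensity.size)
        else:
            self.frames = np.asarray(self.frames, dtype=int)
        if self.frames.size != self.intensity.size:
            raise ValueError("frames and intensity must have equal length")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.excluded = frozenset(int(f) for f in self.excluded)

    @property
    def n_frames(self) -> int:
        return int(self.intensity.size)

    @property
    def time_s(self) -> np.ndarray:
        return self.frames * float(self.frame_interval)

    def valid_mask(self) -> np.ndarray:
        ok = np.ones(self.n_frames, dtype=bool)
        for f in self.excluded:
            idx = np.nonzero(self.frames == f)[0]
            ok[idx] = False
        return ok

    def replace(self, **kw) -> "Trajectory":
        data = dict(nucleus_id=self.nucleus_id, intensity=self.intensity,
                    frame_interval=self.frame_interval, frames=self.frames,
                    excluded=self.excluded,
                    baseline_corrected=self.baseline_corrected)
        data.update(kw)
        return Trajectory(**data)


def trajectories_to_dataframe(trajs: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in trajs:
        for f, v in zip(tr.frames, tr.intensity):
            rows.append((tr.nucleus_id, int(f), f * tr.frame_interval,
                         float(v), int(f) in tr.excluded))
    return pd.DataFrame(rows, columns=["nucleus_id", "frame", "time_s",
                                       "intensity", "excluded"])
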