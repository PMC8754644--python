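"""Linking segmented nuclei into lineages by minimal centroid displacement.

For each adjacent frame pair, candidate assignments are taken greedily in
ascending centroid-distance order, separately forward (t -> t+1) and
backward (t+1 -> t); only assignments agreed by both passes are kept, and
any assignment farther than ``max_disp`` is refused, ending one track and
starting another.  Short interruptions (an empty or failed frame) are
bridged afterwards: a track may resume after a gap of at most ``max_gap``
missing frames; longer gaps split the lineage.

Ties in distance are broken deterministically by the lower label index.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .core import LabelMask, Track

__all__ = ["link"]


def _centroids(labels: np.ndarray) -> dict[int, tuple[float, float]]:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return {}
    cents = ndi.center_of_mass(labels > 0, labels, ids)
    return {int(i): (float(c[0]), float(c[1])) for i, c in zip(ids, cents)}


def _greedy_pairs(a: dict[int, tuple[float, float]],
                  b: dict[int, tuple[float, float]],
                  max_disp: float) -> set[tuple[int, int]]:
    """Greedy one-to-one matching a->b in ascending distance order."""
    cand = []
    for la, (ya, xa) in a.items():
        for lb, (yb, xb) in b.items():
            d = np.hypot(ya - yb, xa - xb)
            if d <= max_disp:
                cand.append((d, la, lb))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out: set[tuple[int, int]] = set()
    for _, la, lb in cand:
        if la in used_a or lb in used_b:
            continue
        used_a.add(la)
        used_b.add(lb)
        out.add((la, lb))
    return out


def link(masks: list[LabelMask] | np.ndarray, max_disp: float,
         max_gap: int = 2) -> list[Track]:
    """Link per-frame label masks into tracks.

    Parameters
    ----------
    masks : list of LabelMask or (T, Y, X) label array
    max_disp : float
        Displacement gate in pixels; assignments beyond it are refused.
        A sensible default is the nucleus radius.
    max_gap : int
        Longest run of missing frames a lineage may bridge (gap entries are
        flagged on the resuming point).  Longer gaps split the track.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if isinstance(masks, np.ndarray):
        frames = [masks[t] for t in range(masks.shape[0])]
    else:
        frames = [m.labels for m in masks]
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    cents = [_centroids(f) for f in frames]
    T = len(frames)

    # reconciled adjacent-frame links
    links: list[set[tuple[int, int]]] = []
    for t in range(T - 1):
        fwd = _greedy_pairs(cents[t], cents[t + 1], max_disp)
        bwd = _greedy_pairs(cents[t + 1], cents[t], max_disp)
        links.append(fwd & {(la, lb) for lb, la in bwd})

    # assemble chains
    tracks: list[Track] = []
    open_by_label: dict[int, Track] = {}  # label at current frame -> track
    for t in range(T):
        new_open: dict[int, Track] = {}
        matched_next: dict[int, int] = dict(links[t]) if t < T - 1 else {}
        for lab in sorted(cents[t]):
            tr = open_by_label.get(lab)
            if tr is None:
                tr = Track(nucleus_id=0)
                tr.append(t, lab, cents[t][lab])
                tracks.append(tr)
            nxt = matched_next.get(lab)
            if nxt is not None:
                new_open[nxt] = tr
        for nxt, tr in new_open.items():
            if t + 1 < T:
                tr.append(t + 1, nxt, cents[t + 1][nxt])
        open_by_label = new_open

    # bridge short gaps: join a track ending at frame f to one starting at
    # f + g + 1 (1 <= g <= max_gap) when the displacement stays in gate
    if max_gap > 0:
        merged = True
        while merged:
            merged = False
            ends = {}
            starts = {}
            for tr in tracks:
                ends.setdefault(tr.end_frame, []).append(tr)
                starts.setdefault(tr.start_frame, []).append(tr)
            cand = []
            for f, enders in ends.items():
                for g in range(1, max_gap + 1):
                    for tr2 in starts.get(f + g + 1, []):
                        for tr1 in enders:
                            if tr1 is tr2:
                                continue
                            y1, x1 = tr1.centroids[-1]
                            y2, x2 = tr2.centroids[0]
                            d = np.hypot(y1 - y2, x1 - x2)
                            if d <= max_disp * (g + 1):
                                cand.append((d, tr1.labels[-1],
                                             tr2.labels[0], tr1, tr2))
            cand.sort(key=lambda c: (c[0], c[1], c[2]))
            used: set[int] = set()
            for d, _, _, tr1, tr2 in cand:
                if id(tr1) in used or id(tr2) in used:
                    continue
                used.add(id(tr1))
                used.add(id(tr2))
                first = True
                for f, lab, c, g in zip(tr2.frames, tr2.labels,
                                        tr2.centroids, tr2.gap_flags):
                    tr1.append(f, lab, c, gap=g or first)
                    first = False
                tracks.remove(tr2)
                merged = True

    tracks.sort(key=lambda tr: (tr.start_frame, tr.labels[0]))
    for i, tr in enumerate(tracks):
        tr.nucleus_id = i + 1
    return tracks
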