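"""Shared fixtures: small rendered fields reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from ms2burst import FieldParams, TelegraphParams, render_movie


@pytest.fixture(scope="session")
def small_field():
    """Noisy 30-nuclei field, 8 frames: enough to exercise segmentation,
    tracking and quantification without dominating the suite runtime."""
    fp = FieldParams(image_shape=(250, 250), n_nuclei=30, noise_sd=50.0,
                     drift_sd=0.3)
    tg = TelegraphParams(k_on=0.4, k_off=0.8, r_load=40.0, dwell=1.2,
                         unit_intensity=100.0, n_frames=8)
    movie, truth = render_movie(fp, tg, seed=7)
    return fp, tg, movie, truth


@pytest.fixture(scope="session")
def noiseless_field():
    """Noise-free 12-nuclei field for exact round-trip checks."""
    fp = FieldParams(image_shape=(200, 200), n_nuclei=12, noise_sd=0.0,
                     drift_sd=0.0)
    tg = TelegraphParams(k_on=0.4, k_off=0.8, r_load=40.0, dwell=1.2,
                         unit_intensity=100.0, n_frames=10)
    movie, truth = render_movie(fp, tg, seed=3)
    return fp, tg, movie, truth


def pair_tracks_to_truth(tracks, truth, max_dist=3.0):
    """Match linked tracks to ground-truth nuclei by frame-0 centroid."""
    pairs = {}
    gt0 = {tr.nucleus_id: tr.centroids[0] for tr in truth.tracks}
    for tr in tracks:
        if tr.start_frame != 0:
            continue
        y, x = tr.centroids[0]
        best, bd = None, np.inf
        for nid, (gy, gx) in gt0.items():
            d = np.hypot(y - gy, x - gx)
            if d < bd:
                best, bd = nid, d
        if bd <= max_dist:
            pairs[tr.nucleus_id] = best
    return pairs
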