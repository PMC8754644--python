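"""Telegraph simulator and movie renderer: exactness of the stochastic
construction and consistency of the rendered ground truth."""

import numpy as np
import pytest
from scipy import stats

from ms2burst import (FieldParams, TelegraphParams, fit_spot, locate_spot,
                      render_movie, simulate_trajectory, variant_presets)
from ms2burst.synthetic import VARIANT_PRESETS


def off_intervals(on_intervals):
    return [(b0 - a1) for (_, a1), (b0, _) in
            zip(on_intervals, on_intervals[1:])]


class TestSimulateTrajectory:
    def test_never_activating_promoter_is_silent(self):
        p = TelegraphParams(k_on=0.0, noise_sd=0.0, n_frames=200)
        traj, on = simulate_trajectory(p, seed=0)
        assert on == []
        assert np.all(traj.intensity == 0.0)

    def test_permanently_on_reaches_loading_steady_state(self):
        p = TelegraphParams(k_on=0.5, k_off=0.0, r_load=10.0, dwell=1.5,
                            unit_intensity=100.0, noise_sd=0.0,
                            onset_delay=0.0, n_frames=1200)
        traj, on = simulate_trajectory(p, seed=1)
        assert len(on) == 1
        assert on[0][1] == pytest.approx(p.total_minutes * 60.0)
        # steady state: r_load * dwell transcripts on average after the rise
        rise_frames = int(np.ceil(p.dwell * 60 / p.frame_interval)) + 1
        start = int(on[0][0] / p.frame_interval) + rise_frames
        level = traj.intensity[start:].mean()
        assert level == pytest.approx(
            p.r_load * p.dwell * p.unit_intensity, rel=0.10)

    def test_off_durations_are_exponential_with_rate_k_on(self):
        # one long trace supplying >= 10,000 OFF intervals
        p = TelegraphParams(k_on=0.5, k_off=1.0, r_load=0.0, noise_sd=0.0,
                            n_frames=115000)
        _, on = simulate_trajectory(p, seed=0)
        offs = np.array(off_intervals(on)) / 60.0  # minutes
        assert offs.size >= 10000
        mle_rate = 1.0 / offs.mean()
        assert mle_rate == pytest.approx(0.5, rel=0.05)
        ks = stats.kstest(offs, "expon", args=(0.0, offs.mean()))
        assert ks.pvalue > 0.01

    def test_burst_rate_matches_telegraph_prediction(self):
        p = TelegraphParams(k_on=0.5, k_off=1.0, r_load=0.0, noise_sd=0.0,
                            n_frames=36000)  # 10,080 minutes
        _, on = simulate_trajectory(p, seed=2)
        rate = len(on) / p.total_minutes
        expected = p.k_on * p.k_off / (p.k_on + p.k_off)
        assert rate == pytest.approx(expected, rel=0.05)

    def test_fixed_seed_is_bit_reproducible(self):
        p = TelegraphParams(noise_sd=50.0, n_frames=300)
        t1, on1 = simulate_trajectory(p, seed=42)
        t2, on2 = simulate_trajectory(p, seed=42)
        assert np.array_equal(t1.intensity, t2.intensity)
        assert on1 == on2

    @pytest.mark.parametrize("bad", [dict(k_on=-1.0), dict(dwell=np.nan),
                                     dict(n_frames=0),
                                     dict(frame_interval=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            TelegraphParams(**bad)


class TestRenderMovie:
    def test_constant_trajectory_rendered_dot_integral(self):
        # single static nucleus, no noise: the rendered dot integrates to the
        # trajectory value (permanently ON promoter at steady state varies,
        # so check rendered pixels against the true trajectory directly)
        fp = FieldParams(image_shape=(100, 100), n_nuclei=1, drift_sd=0.0,
                         noise_sd=0.0)
        tg = TelegraphParams(k_on=10.0, k_off=0.0, r_load=40.0, dwell=1.0,
                             unit_intensity=100.0, noise_sd=0.0, n_frames=6)
        movie, truth = render_movie(fp, tg, seed=5)
        for t in range(6):
            v = truth.trajectories[0].intensity[t]
            if v < 500:   # quantization dominates tiny dots
                continue
            z, y, x = (int(round(c)) for c in truth.spot_centers[0, t])
            plane = movie[t, z, 1].astype(float) - fp.ms2_bg
            win = plane[y - 9:y + 10, x - 9:x + 10]
            assert win.sum() == pytest.approx(v, rel=0.01)

    def test_nucleus_count_conserved_in_every_frame(self, small_field):
        _, _, _, truth = small_field
        for t in range(truth.masks.shape[0]):
            assert len(np.unique(truth.masks[t])) - 1 == 30

    def test_fitted_spot_recovers_rendered_integral(self, noiseless_field):
        _, _, movie, truth = noiseless_field
        traj = truth.trajectories[0].intensity
        t = int(np.argmax(traj))
        z, y, x = locate_spot(movie[t, :, 1], truth.masks[t], 1)
        fit = fit_spot(movie[t, z, 1].astype(float), (y, x))
        assert fit.valid
        assert fit.integral == pytest.approx(traj[t], rel=0.01)

    def test_stripe_pattern_silences_outside_nuclei(self):
        active = TelegraphParams(k_on=5.0, k_off=0.5, r_load=40.0,
                                 dwell=1.0, unit_intensity=100.0, n_frames=5)
        fp = FieldParams(image_shape=(200, 200), n_nuclei=25, noise_sd=0.0,
                         stripe_pattern=[((0.0, 0.3), active),
                                         ((0.6, 0.8), active)])
        movie, truth = render_movie(fp, None, seed=9)
        w = fp.image_shape[1]
        for tr, traj in zip(truth.tracks, truth.trajectories):
            frac = tr.centroids[0][1] / w
            inside = (0.0 <= frac < 0.3) or (0.6 <= frac < 0.8)
            if not inside:
                assert np.all(traj.intensity == 0.0)

    def test_overcrowded_field_raises(self):
        fp = FieldParams(image_shape=(60, 60), n_nuclei=50)
        with pytest.raises(RuntimeError, match="1000 attempts"):
            render_movie(fp, TelegraphParams(n_frames=2), seed=0)

    def test_rendering_is_reproducible(self):
        fp = FieldParams(image_shape=(120, 120), n_nuclei=5, noise_sd=30.0)
        tg = TelegraphParams(n_frames=3)
        m1, _ = render_movie(fp, tg, seed=11)
        m2, _ = render_movie(fp, tg, seed=11)
        assert np.array_equal(m1, m2)


class TestVariantPresets:
    def test_tata_mutant_reduces_amplitude_and_frequency(self):
        wt, mtata = variant_presets("WT"), variant_presets("mTATA")
        assert wt.r_load * wt.dwell > mtata.r_load * mtata.dwell
        assert wt.k_on > mtata.k_on

    def test_zelda_shortens_onset_delay(self):
        assert variant_presets("Zelda").onset_delay < \
            variant_presets("WT").onset_delay

    def test_mte_is_milder_than_dpe(self):
        assert variant_presets("mMTE").k_on > variant_presets("mDPE").k_on

    def test_downstream_mutants_delay_onset_and_reduce_frequency(self):
        wt = variant_presets("WT")
        for name in ("mInr", "mMTE", "mDPE"):
            v = variant_presets(name)
            assert v.k_on < wt.k_on
            assert v.onset_delay > wt.onset_delay

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(KeyError, match="WT"):
            variant_presets("mGAGA-typo")
        assert set(VARIANT_PRESETS) == {"WT", "mTATA", "mInr", "mMTE",
                                        "mDPE", "Zelda"}
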