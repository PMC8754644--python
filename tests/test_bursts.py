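"""Burst calling: smoothing conventions, the five calling rules against an
independent brute-force oracle, and per-nucleus statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ms2burst import (Trajectory, burst_stats, call_bursts, group_threshold,
                      simulate_trajectory, smooth, TelegraphParams)
from _reference import oracle_call_bursts


class TestSmooth:
    def test_impulse_with_truncated_edges(self):
        out = smooth(np.array([0.0, 0, 10, 0, 0]), 5)
        assert np.allclose(out, [10 / 3, 10 / 4, 2.0, 10 / 4, 10 / 3])

    def test_constant_trace_unchanged(self):
        assert np.allclose(smooth(np.full(20, 3.3), 5), 3.3)

    def test_window_one_is_identity(self):
        x = np.random.default_rng(0).uniform(size=30)
        assert np.array_equal(smooth(x, 1), x)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.zeros(3), 5)

    @given(st.lists(st.floats(0, 1e4), min_size=5, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_smoothing_stays_within_data_range(self, vals):
        x = np.asarray(vals)
        out = smooth(x, 5)
        assert np.all(out >= x.min() - 1e-9)
        assert np.all(out <= x.max() + 1e-9)


class TestCallBursts:
    def test_silent_trace_yields_no_bursts(self):
        call = call_bursts(np.zeros(50), threshold=10.0)
        assert call.n_bursts == 0

    def test_plateau_burst_end_rule_and_shift(self):
        # 10 zeros, 20 frames at 100, 10 zeros; threshold 10:
        # burst opens at frame 10, closes (exclusive) at frame 30 where the
        # signal first drops below 55% of the peak, then shifts +2
        trace = np.concatenate([np.zeros(10), np.full(20, 100.0),
                                np.zeros(10)])
        call = call_bursts(trace, threshold=10.0)
        assert call.n_bursts == 1
        b = call.bursts[0]
        assert (b.start, b.end) == (12, 31)
        assert b.peak_value == 100.0

    def test_short_spike_filtered_as_false_positive(self):
        trace = np.zeros(40)
        trace[20:23] = 100.0   # 3 frames above threshold
        call = call_bursts(trace, threshold=10.0)
        assert call.n_bursts == 0

    def test_initial_decline_not_a_burst(self):
        # already decaying when detection starts: not a burst
        trace = np.concatenate([np.linspace(100, 20, 8), np.zeros(30)])
        call = call_bursts(trace, threshold=10.0)
        assert call.n_bursts == 0

    def test_burst_pushed_off_end_discarded(self):
        trace = np.zeros(20)
        trace[18:] = 100.0
        call = call_bursts(trace, threshold=10.0)
        assert call.n_bursts == 0

    def test_matches_brute_force_oracle_on_telegraph_traces(self):
        rng = np.random.default_rng(2024)
        for _ in range(120):
            p = TelegraphParams(
                k_on=rng.uniform(0.05, 1.0), k_off=rng.uniform(0.3, 2.0),
                r_load=rng.uniform(20, 120), dwell=rng.uniform(0.3, 2.0),
                unit_intensity=100.0, noise_sd=rng.uniform(0, 300),
                n_frames=int(rng.integers(30, 300)))
            traj, _ = simulate_trajectory(p, rng)
            s = smooth(traj.intensity, 5)
            thr = max(0.1 * s.max(), 1e-6)
            got = [(b.start, b.end) for b in call_bursts(s, thr).bursts]
            assert got == oracle_call_bursts(s, thr)

    def test_matches_oracle_on_adversarial_integer_traces(self):
        # short integer traces hammer the edge rules (ties at the threshold,
        # exact 55% drops, bursts at either end)
        rng = np.random.default_rng(99)
        for _ in range(300):
            s = rng.integers(0, 6, size=int(rng.integers(6, 25))).astype(float)
            got = [(b.start, b.end)
                   for b in call_bursts(s, 2.0, min_len=3, shift=2).bursts]
            assert got == oracle_call_bursts(s, 2.0, min_len=3, shift=2)

    def test_min_len_filter_does_not_bias_surviving_durations(self):
        # bursts already >= min_len are kept verbatim: filtering only removes
        # short events, never reshapes long ones
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = rng.integers(0, 8, size=60).astype(float)
            with_filter = call_bursts(s, 2.0, min_len=5)
            no_filter = call_bursts(s, 2.0, min_len=1)
            kept = [(b.start, b.end) for b in with_filter.bursts]
            assert set(kept) <= {(b.start, b.end) for b in no_filter.bursts}
            assert all(b.length >= 5 for b in with_filter.bursts)


class TestBurstStats:
    def test_amplitude_and_duration_arithmetic(self):
        trace = np.zeros(40)
        trace[10:20] = 50.0
        traj = Trajectory(1, trace, 16.8)
        call = call_bursts(trace, threshold=5.0, shift=0)
        st_ = burst_stats(call, traj, trace)
        assert st_.n_bursts == 1
        assert st_.amplitude == 50.0
        assert st_.duration == pytest.approx(10 * 16.8)

    def test_induction_rate_definition(self):
        # two bursts, first at 100 s, trace ends at 700 s -> 2/600 s = 0.2/min
        dt = 100.0
        trace = np.zeros(8)
        trace[1:3] = 100.0
        trace[5:7] = 100.0
        traj = Trajectory(1, trace, dt)
        call = call_bursts(trace, threshold=10.0, min_len=2, shift=0)
        st_ = burst_stats(call, traj, trace)
        assert st_.n_bursts == 2
        assert st_.t_first == pytest.approx(100.0)
        assert st_.induction_rate == pytest.approx(2 / 600.0 * 60.0)

    def test_total_output_rectangle_rule(self):
        traj = Trajectory(1, np.ones(100), 16.8)
        st_ = burst_stats(call_bursts(np.ones(100), 0.5), traj, np.ones(100))
        assert st_.total_output == pytest.approx(1680.0)

    def test_silent_nucleus_marked_undefined(self):
        traj = Trajectory(1, np.zeros(30), 16.8)
        st_ = burst_stats(call_bursts(np.zeros(30), 1.0), traj)
        assert st_.n_bursts == 0
        assert np.isnan(st_.amplitude) and np.isnan(st_.t_first)
        assert np.isnan(st_.induction_rate)

    def test_off_durations_are_gaps_between_bursts(self):
        trace = np.zeros(30)
        trace[2:10] = 100.0
        trace[20:28] = 100.0
        traj = Trajectory(1, trace, 10.0)
        call = call_bursts(trace, threshold=10.0, shift=0)
        st_ = burst_stats(call, traj, trace)
        assert len(st_.off_durations) == 1
        gap_frames = call.bursts[1].start - call.bursts[0].end - 1
        assert st_.off_durations[0] == pytest.approx(gap_frames * 10.0)


class TestGroupThreshold:
    def test_default_is_ten_percent_of_group_max(self):
        trajs = [Trajectory(1, np.array([0.0, 200.0, 0, 0, 0]), 16.8),
                 Trajectory(2, np.array([0.0, 50.0, 0, 0, 0]), 16.8)]
        # max of the *smoothed* traces: impulse 200 smooths to 200/3
        assert group_threshold(trajs, window=1) == pytest.approx(20.0)

    def test_config_override_wins(self):
        trajs = [Trajectory(1, np.full(10, 100.0), 16.8)]
        assert group_threshold(trajs, override=15.0) == 15.0

    def test_independent_thresholds_per_experiment_set(self):
        set1 = [Trajectory(1, np.full(10, 100.0), 16.8)]
        set2 = [Trajectory(1, np.full(10, 300.0), 16.8)]
        assert group_threshold(set2) == 3 * group_threshold(set1)

    def test_all_zero_group_rejected(self):
        with pytest.raises(ValueError):
            group_threshold([Trajectory(1, np.zeros(10), 16.8)])
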