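"""Fluorescence processing: dF/F, dR/R, ROI extraction, correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormstate.calcium import (
    DegenerateBaselineError,
    FluorTrace,
    delta_f_over_f,
    delta_r_over_r,
    displacement_behavior,
    extract_neuron_trace,
    extract_ris_trace,
    state_fluorescence_summary,
    windowed_correlation,
)
from wormstate.sleep import BoutSet
from wormstate.synthetic import BoutSchedule, simulate_fluorescence


def make_trace(dff, fps=1.0):
    """Hand-assembled FluorTrace for testing ratio logic in isolation."""
    dff = np.asarray(dff, dtype=float)
    return FluorTrace(
        times_s=np.arange(dff.size) / fps,
        F=1 + dff,
        F0=np.ones_like(dff),
        dFF=dff,
    )


class TestNeuronRoi:
    def test_uniform_frame_gives_its_value(self):
        video = np.full((3, 20, 20), 7.0)
        assert extract_neuron_trace(video, (10, 10), 4).tolist() == [7.0] * 3

    def test_half_bright_roi_averages(self):
        frame = np.zeros((20, 20))
        frame[:, 10:] = 8.0  # ROI rows 6:14, cols 6:14 -> half at 8
        out = extract_neuron_trace(frame[None], (10, 10), 4)
        assert out[0] == pytest.approx(4.0)

    def test_clipped_roi_raises(self):
        with pytest.raises(ValueError):
            extract_neuron_trace(np.zeros((2, 20, 20)), (2, 10), 4)

    def test_tracks_truth_signal_through_noise(self, rng):
        n = 100
        s = 50 + 40 * np.sin(np.linspace(0, 6, n))
        video = rng.normal(0, 1.0, size=(n, 16, 16))
        video[:, 4:12, 4:12] += s[:, None, None]
        F = extract_neuron_trace(video, (8, 8), 4)
        assert np.corrcoef(F, s)[0, 1] > 0.99


class TestRisRoi:
    def test_mean_of_20_largest(self):
        frame = np.zeros((31, 31))
        frame[3:7, 3:8] = 100.0  # exactly 20 pixels of 100
        assert extract_ris_trace(frame, (15, 15)) == pytest.approx(100.0)

    def test_uniform_window(self):
        assert extract_ris_trace(np.full((31, 31), 5.5), (15, 15)) == pytest.approx(5.5)

    def test_top20_order_statistics(self):
        frame = np.arange(1, 626, dtype=float).reshape(25, 25)
        # values 1..625; top 20 are 606..625, mean 615.5
        assert extract_ris_trace(frame, (12, 12)) == pytest.approx(615.5)

    def test_edge_window_pads_with_warning(self):
        frame = np.full((30, 30), 3.0)
        with pytest.warns(UserWarning):
            assert extract_ris_trace(frame, (2, 2)) == pytest.approx(3.0)


class TestDeltaFOverF:
    def test_hand_example_running_minimum(self):
        tr = delta_f_over_f(np.array([5.0, 4.0, 6.0]), smooth_s=0)
        assert tr.F0.tolist() == [5.0, 4.0, 4.0]
        assert tr.dFF.tolist() == [0.0, 0.0, 0.5]

    def test_monotone_series_baseline_is_first_value(self):
        F = np.array([2.0, 2.0, 3.0, 5.0, 8.0])
        tr = delta_f_over_f(F, smooth_s=0)
        assert np.allclose(tr.dFF, F / F[0] - 1)

    def test_constant_series_gives_zero(self):
        tr = delta_f_over_f(np.full(50, 9.0), smooth_s=0)
        assert np.allclose(tr.dFF, 0.0)

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(DegenerateBaselineError):
            delta_f_over_f(np.array([1.0, -0.5, 2.0]), smooth_s=0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_invariants_on_random_positive_traces(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.uniform(0.5, 10.0, size=int(rng.integers(3, 200)))
        tr = delta_f_over_f(F, fps=5, smooth_s=rng.choice([0.0, 3.0]))
        assert np.all(np.diff(tr.F0) <= 0)
        assert np.all(tr.dFF >= 0)
        # invariance under F -> cF
        tr2 = delta_f_over_f(4.2 * F, fps=5, smooth_s=0)
        tr1 = delta_f_over_f(F, fps=5, smooth_s=0)
        assert np.allclose(tr1.dFF, tr2.dFF)


class TestDeltaROverR:
    def test_identity_channels_give_zero_drr(self):
        dff = np.linspace(0.01, 0.8, 60)
        tr = delta_r_over_r(make_trace(dff), make_trace(dff), denom_floor=0.01)
        assert np.allclose(tr.R, 1.0)
        assert tr.R0 == pytest.approx(1.0)
        assert np.allclose(tr.dRR, 0.0)

    def test_r0_against_percentile_oracle(self):
        R = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        # brute-force 20th percentile: k = 0.2 * 4 = 0.8 between sorted[0..1]
        k = 0.2 * (R.size - 1)
        srt = np.sort(R)
        oracle = srt[0] + (k - 0) * (srt[1] - srt[0])
        gcamp = make_trace(R * 0.5)
        mkate = make_trace(np.full_like(R, 0.5))
        tr = delta_r_over_r(gcamp, mkate, denom_floor=0.01)
        assert np.allclose(tr.R, R)
        assert tr.R0 == pytest.approx(oracle)

    def test_drr_invariant_to_common_rescaling_of_r(self):
        rng = np.random.default_rng(3)
        dff_g = rng.uniform(0.05, 1.0, 100)
        dff_m = rng.uniform(0.05, 1.0, 100)
        tr1 = delta_r_over_r(make_trace(dff_g), make_trace(dff_m))
        tr2 = delta_r_over_r(make_trace(3 * dff_g), make_trace(dff_m))
        assert np.allclose(tr2.dRR, tr1.dRR)

    def test_all_zero_mkate_raises(self):
        with pytest.raises(DegenerateBaselineError):
            delta_r_over_r(make_trace(np.ones(10)), make_trace(np.zeros(10)))


class TestDisplacementBehavior:
    def test_static_positions_give_zero(self):
        pos = np.zeros((50, 3, 2))
        out = displacement_behavior(pos, fps=5, normalize=False)
        assert np.allclose(out, 0.0)

    def test_translation_gives_pythagorean_displacement(self):
        steps = np.arange(20)[:, None, None] * np.array([3.0, 4.0])
        pos = np.tile(steps, (1, 5, 1))
        out = displacement_behavior(pos, fps=5, normalize=False)
        assert np.allclose(out, 5.0)

    def test_one_moving_of_ten_gives_tenth(self):
        pos = np.zeros((10, 10, 2))
        pos[:, 0, 1] = np.arange(10) * 7.0
        out = displacement_behavior(pos, fps=5, normalize=False)
        assert np.allclose(out, 0.7)

    def test_missing_positions_warn_and_exclude(self):
        pos = np.zeros((10, 2, 2))
        pos[:, 1, 0] = np.arange(10.0)
        pos[5, 1, :] = np.nan
        with pytest.warns(UserWarning):
            out = displacement_behavior(pos, fps=5, normalize=False)
        assert out[0] == pytest.approx(0.5)  # (0 + 1)/2
        assert out[4] == pytest.approx(0.0)  # NaN neuron excluded


class TestStateSummary:
    def test_two_level_series(self):
        bouts = BoutSet("w", [(10.0, 20.0)], 0.2, 30, 15, 30.0)
        series = np.where((np.arange(30) >= 10) & (np.arange(30) < 20), 0.2, 1.0)
        wake, sleep = state_fluorescence_summary(series, bouts, fps=1)
        assert (wake, sleep) == (pytest.approx(1.0), pytest.approx(0.2))

    def test_no_bouts_gives_none_sleep(self):
        bouts = BoutSet("w", [], 0.2, 30, 15, 10.0)
        wake, sleep = state_fluorescence_summary(np.ones(10), bouts, fps=1)
        assert sleep is None

    def test_ris_like_channel_higher_in_sleep(self):
        schedule = BoutSchedule([(100.0, 300.0)], [], 600.0)
        traces, _ = simulate_fluorescence(
            schedule, n_neurons=3, fps=5, ris_like=True, noise_sd=1.0, seed=0
        )
        bouts = BoutSet("w", schedule.intervals, 0.2, 30, 15, 600.0)
        wake, sleep = state_fluorescence_summary(traces["ris"], bouts, fps=5)
        assert sleep > wake
        # ordinary neurons show the opposite
        wake_n, sleep_n = state_fluorescence_summary(traces["neurons"][0], bouts, fps=5)
        assert sleep_n < wake_n


class TestWindowedCorrelation:
    def test_exact_anticorrelation_gives_minus_one(self, rng):
        b = rng.normal(size=1200)
        r, _ = windowed_correlation(b, -b, window_s=60, fps=1)
        assert np.allclose(r, -1.0)

    def test_null_shuffle_distribution_centered_near_zero(self, rng):
        b = rng.normal(size=4000)
        f = rng.normal(size=4000)
        r, shuffled = windowed_correlation(
            b, f, window_s=200, fps=1, n_shuffles=200, seed=0
        )
        n_windows = 20
        se = shuffled.std() / np.sqrt(n_windows)
        assert abs(shuffled.mean()) < 3 * se + 0.05

    def test_identity_exclusion_changes_little_with_many_windows(self, rng):
        b = rng.normal(size=3000)
        f = -b + rng.normal(0, 0.2, size=3000)
        _, incl = windowed_correlation(b, f, 300, 1, n_shuffles=300, seed=1)
        _, excl = windowed_correlation(
            b, f, 300, 1, n_shuffles=300, seed=1, exclude_identity=True
        )
        # identity pairings are 1/n_windows of slots; their -1 contribution
        # shifts the mean by about that fraction and no more
        assert abs(incl.mean() - excl.mean()) < 2.0 / 10

    def test_constant_window_skipped_with_warning(self):
        b = np.concatenate([np.ones(50), np.random.default_rng(0).normal(size=50)])
        f = np.random.default_rng(1).normal(size=100)
        with pytest.warns(UserWarning):
            r, _ = windowed_correlation(b, f, window_s=50, fps=1)
        assert r.size == 1

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError):
            windowed_correlation(np.ones(10), np.ones(11), 5, 1)
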