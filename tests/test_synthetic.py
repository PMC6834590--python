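"""Ground-truth generators: schedules, videos, fluorescence, puncta."""

import numpy as np
import pytest

from wormstate.posture import dimensionless_curvature_of_points, resample_centerline
from wormstate.synthetic import (
    BoutSchedule,
    SyntheticWormConfig,
    render_puncta_image,
    render_worm_video,
    sample_bout_schedule,
    simulate_activity_trace,
    simulate_fluorescence,
)


class TestBoutSchedule:
    def test_truncation_guarantees_minimum_bout(self):
        sch = sample_bout_schedule(600, 120, 180, 30, 0, seed=1)
        assert all(e - s >= 30 for s, e in sch.intervals)

    def test_degenerate_wake_rate_gives_empty_schedule(self):
        sch = sample_bout_schedule(600, 120, 1e9, 30, 0, seed=1)
        assert len(sch.intervals) <= 1

    def test_twitches_inside_intervals_and_short(self):
        sch = sample_bout_schedule(7200, 240, 240, 30, 2.0, seed=3)
        assert sch.twitches  # rate high enough to see some
        for t, d in sch.twitches:
            assert 1.0 <= d <= 10.0
            assert any(s <= t and t + d <= e for s, e in sch.intervals)

    def test_mean_bout_length_matches_truncated_exponential(self):
        # truncated exponential: mean = min_bout + scale by memorylessness;
        # exclude intervals censored by the recording end
        lengths = []
        for seed in range(100):
            sch = sample_bout_schedule(3600, 120, 240, 30, 0.5, seed=seed)
            lengths += [
                e - s for s, e in sch.intervals if e < sch.duration_s - 1e-9
            ]
        assert np.mean(lengths) == pytest.approx(120 + 30, rel=0.2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sample_bout_schedule(-5, 120, 180, 30, 0)
        with pytest.raises(ValueError):
            BoutSchedule([(0.0, 50.0)], [(10.0, 16.0)], 100.0)  # twitch >= 15 s
        with pytest.raises(ValueError):
            BoutSchedule([(0.0, 50.0)], [(60.0, 5.0)], 100.0)  # twitch outside

    def test_determinism(self):
        a = sample_bout_schedule(3600, 240, 240, 30, 0.5, seed=42)
        b = sample_bout_schedule(3600, 240, 240, 30, 0.5, seed=42)
        assert a.intervals == b.intervals and a.twitches == b.twitches


class TestActivityTraceGenerator:
    def test_quiescent_samples_low_wake_samples_high(self):
        sch = BoutSchedule([(100.0, 300.0)], [], 600.0)
        raw = simulate_activity_trace(sch, fps=3, seed=0)
        quiet = sch.state_mask(raw.size, 3)
        assert raw[quiet].max() < raw[~quiet].min()

    def test_no_twitch_schedule_has_no_in_bout_spikes(self):
        sch = sample_bout_schedule(3600, 240, 240, 30, 0, seed=5)
        raw = simulate_activity_trace(sch, fps=3, seed=6)
        quiet = sch.state_mask(raw.size, 3)
        assert np.ptp(raw[quiet]) == 0.0

    def test_determinism(self):
        sch = sample_bout_schedule(1200, 240, 240, 30, 0.5, seed=7)
        a = simulate_activity_trace(sch, seed=8)
        b = simulate_activity_trace(sch, seed=8)
        assert np.array_equal(a, b)


class TestWormVideo:
    def test_frozen_posture_frames_identical_without_noise(self):
        sch = BoutSchedule([(0.0, 30.0)], [], 30.0)
        config = SyntheticWormConfig(noise_sd=0.0, seed=1)
        video, _ = render_worm_video(config, sch)
        assert all(np.array_equal(video[0], f) for f in video[1:])

    def test_wake_frames_all_differ(self):
        sch = BoutSchedule([], [], 20.0)
        config = SyntheticWormConfig(noise_sd=0.0, seed=1)
        video, _ = render_worm_video(config, sch)
        diffs = (np.diff(video.astype(int), axis=0) != 0).sum(axis=(1, 2))
        assert np.all(diffs > 0)

    def test_twitch_displaces_frozen_posture(self):
        sch = BoutSchedule([(0.0, 60.0)], [(20.0, 5.0)], 60.0)
        config = SyntheticWormConfig(noise_sd=0.0, seed=1)
        video, _ = render_worm_video(config, sch)
        fps = config.fps
        assert np.array_equal(video[0], video[10])
        assert not np.array_equal(video[0], video[int(22 * fps)])

    def test_sleep_curvature_matches_configured_gain(self):
        sch = BoutSchedule([(0.0, 10.0)], [], 20.0)
        config = SyntheticWormConfig(sleep_curvature_gain=1.15, seed=2)
        _, truth = render_worm_video(config, sch)
        quiet = sch.state_mask(len(truth.centerlines), config.fps)
        vals = np.array(
            [
                dimensionless_curvature_of_points(resample_centerline(c))
                for c in truth.centerlines
            ]
        )
        ratio = vals[quiet].mean() / vals[~quiet].mean()
        assert ratio == pytest.approx(1.15, rel=0.02)

    def test_worm_longer_than_chamber_rejected(self):
        with pytest.raises(ValueError):
            SyntheticWormConfig(chamber_px=(50, 60), worm_length_px=70)

    def test_determinism(self):
        sch = BoutSchedule([(2.0, 8.0)], [], 10.0)
        config = SyntheticWormConfig(noise_sd=2.0, seed=9)
        v1, _ = render_worm_video(config, sch)
        v2, _ = render_worm_video(config, sch)
        assert np.array_equal(v1, v2)


class TestFluorescence:
    def test_noiseless_all_wake_traces_constant(self):
        sch = BoutSchedule([], [], 100.0)
        traces, _ = simulate_fluorescence(sch, n_neurons=3, fps=5, seed=0)
        assert np.ptp(traces["neurons"], axis=1).max() == 0.0
        assert np.ptp(traces["red"]) == 0.0

    def test_ris_channel_anticorrelated_with_wake(self):
        sch = BoutSchedule([(100.0, 300.0)], [], 600.0)
        traces, _ = simulate_fluorescence(sch, fps=5, ris_like=True, seed=1)
        wake = 1.0 - sch.state_mask(traces["ris"].size, 5)
        assert np.corrcoef(traces["ris"], wake)[0, 1] < 0

    def test_debleached_sleep_wake_ratio_exact(self):
        sch = BoutSchedule([(40.0, 80.0)], [], 120.0)
        traces, _ = simulate_fluorescence(
            sch, n_neurons=2, fps=5, bleach_tau_s=300.0, seed=2, sleep_wake_ratio=0.5
        )
        t = np.arange(traces["neurons"].shape[1]) / 5
        debleached = traces["neurons"][0] / np.exp(-t / 300.0)
        quiet = sch.state_mask(t.size, 5)
        assert debleached[quiet].mean() / debleached[~quiet].mean() == pytest.approx(0.5)

    def test_red_channel_state_independent(self):
        sch = BoutSchedule([(40.0, 80.0)], [], 120.0)
        traces, _ = simulate_fluorescence(sch, fps=5, bleach_tau_s=300.0, seed=3)
        t = np.arange(traces["red"].size) / 5
        assert np.allclose(traces["red"] / np.exp(-t / 300.0), 100.0)


class TestPunctaImages:
    def test_zero_puncta_empty_truth(self):
        _, truth = render_puncta_image(n_puncta=0, seed=0)
        assert truth.puncta_truth == []

    def test_areas_within_range(self):
        _, truth = render_puncta_image(n_puncta=5, area_range_px=(2, 30), seed=1)
        assert len(truth.puncta_truth) == 5
        assert all(2 <= a <= 30 for _, _, a in truth.puncta_truth)

    def test_out_of_range_blobs_rendered_but_excluded_from_truth(self):
        img, truth = render_puncta_image(
            n_puncta=2, seed=2, noise_sd=0.0, out_of_range_areas=(1, 40)
        )
        total_bright = (img > 150).sum()
        assert total_bright == sum(a for _, _, a in truth.puncta_truth) + 41

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="packing"):
            render_puncta_image(shape_px=(60, 60), n_puncta=50, seed=3)

    def test_determinism(self):
        a, _ = render_puncta_image(n_puncta=7, seed=4)
        b, _ = render_puncta_image(n_puncta=7, seed=4)
        assert np.array_equal(a, b)
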