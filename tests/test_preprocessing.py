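"""Windowing arithmetic against brute-force oracles, plus noise rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from musemi import (
    DEFAULT_SESSION_GRID,
    DEFAULT_WINDOW_GRID,
    BandPowerRecording,
    NoiseRules,
    SessionConfig,
    SyntheticConfig,
    average_window,
    build_sample,
    generate_continuous_session,
    generate_dataset,
    generate_trial,
    inject_artifacts,
    points_per_window,
    reject_noisy,
    segment_continuous,
    segment_windows,
    truncate_session,
)


def _recording_of_rows(n, fs=256.0, label="left"):
    ts = np.arange(n) / fs
    values = np.tile(np.arange(n, dtype=float)[:, None], (1, 20))
    return BandPowerRecording(timestamps=ts, values=values, label=label,
                              recording_id="synthetic")


def brute_force_windows(n_rows, window_size, overlap, fs):
    """Independent enumeration of every admissible window start."""
    ppw = max(1, int(round(window_size * fs)))
    hop_seconds = window_size * (1 - overlap)
    ranges = []
    k = 0
    while True:
        start = int(round(k * hop_seconds * fs))
        if start + ppw > n_rows:
            return ranges
        ranges.append((start, start + ppw))
        k += 1


class TestPointsPerWindow:
    @pytest.mark.parametrize("w,rate,expected", [
        (2.5, 256, 640),       # the worked example
        (1 / 256, 256, 1),
        (2, 256, 512),
        (0.025, 256, 6),       # 6.4 rounds down
    ])
    def test_examples(self, w, rate, expected):
        assert points_per_window(w, rate) == expected

    @pytest.mark.parametrize("w,rate", [(0, 256), (2, 0), (-1, 256)])
    def test_non_positive_rejected(self, w, rate):
        with pytest.raises(ValueError):
            points_per_window(w, rate)


class TestTruncateSession:
    def test_head_discard_slice(self):
        rec = _recording_of_rows(20 * 256)
        cfg = SessionConfig(session_size=2, window_size=2, head_discard=2)
        out = truncate_session(rec, cfg)
        assert out.n_rows == 512
        # rows covering seconds [2, 4)
        assert out.values[0, 0] == 512
        assert out.values[-1, 0] == 1023

    def test_full_tail_identity(self):
        rec = _recording_of_rows(4 * 256)
        cfg = SessionConfig(session_size=2, window_size=2, head_discard=2)
        out = truncate_session(rec, cfg)
        np.testing.assert_array_equal(out.values, rec.values[512:])

    def test_17s_usable_2s_session(self):
        rec = _recording_of_rows(17 * 256)
        cfg = SessionConfig(session_size=2, window_size=2, head_discard=0)
        assert truncate_session(rec, cfg).n_rows == 512

    def test_too_short_names_durations(self):
        rec = _recording_of_rows(256)
        cfg = SessionConfig(session_size=2, window_size=2, head_discard=2)
        with pytest.raises(ValueError, match="need .* have"):
            truncate_session(rec, cfg)


class TestSegmentWindows:
    def test_19_windows_for_20s_session(self):
        rec = _recording_of_rows(20 * 256)
        cfg = SessionConfig(session_size=20, window_size=2, head_discard=0)
        ranges = segment_windows(rec, cfg)
        assert len(ranges) == 19
        assert ranges[0] == (0, 512)
        assert ranges[1] == (256, 768)

    def test_single_window_when_equal(self):
        rec = _recording_of_rows(512)
        cfg = SessionConfig(session_size=2, window_size=2, head_discard=0)
        assert segment_windows(rec, cfg) == [(0, 512)]

    def test_zero_overlap_tiles_session(self):
        rec = _recording_of_rows(4 * 256)
        cfg = SessionConfig(session_size=4, window_size=1, head_discard=0,
                            overlap_fraction=0.0)
        ranges = segment_windows(rec, cfg)
        assert len(ranges) == 4
        assert ranges == [(i * 256, (i + 1) * 256) for i in range(4)]

    def test_window_longer_than_session_errors(self):
        rec = _recording_of_rows(100)
        cfg = SessionConfig(session_size=5, window_size=5, head_discard=0)
        with pytest.raises(ValueError, match="longer than"):
            segment_windows(rec, cfg)

    def test_matches_brute_force_over_full_grid(self):
        """Every feasible default-grid cell agrees with independent enumeration."""
        fs = 256.0
        checked = 0
        for S in DEFAULT_SESSION_GRID:
            n_rows = int(round(S * fs))
            for W in DEFAULT_WINDOW_GRID:
                if W > S or max(1, int(round(W * fs))) > n_rows:
                    continue
                rec = _recording_of_rows(n_rows)
                cfg = SessionConfig(session_size=S, window_size=W,
                                    head_discard=0)
                got = segment_windows(rec, cfg)
                assert got == brute_force_windows(n_rows, W, 0.5, fs), (S, W)
                # 2n-1 on divisible cells
                n = S / W
                if abs(n - round(n)) < 1e-9:
                    assert len(got) == 2 * int(round(n)) - 1, (S, W)
                checked += 1
        assert checked > 400

    @given(
        s_idx=st.integers(0, len(DEFAULT_SESSION_GRID) - 1),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    @settings(max_examples=60, deadline=None)
    def test_windows_stay_inside_session(self, s_idx, overlap):
        S = DEFAULT_SESSION_GRID[s_idx]
        n_rows = int(round(S * 256))
        rec = _recording_of_rows(max(n_rows, 1))
        for W in DEFAULT_WINDOW_GRID:
            if W > S:
                continue
            cfg = SessionConfig(session_size=S, window_size=W,
                                head_discard=0, overlap_fraction=overlap)
            try:
                ranges = segment_windows(rec, cfg)
            except ValueError:
                continue
            assert all(0 <= a < b <= rec.n_rows for a, b in ranges)


class TestAverageWindow:
    def test_mean_of_constants(self):
        rec = BandPowerRecording(
            timestamps=np.arange(10) / 256.0,
            values=np.tile(np.arange(20.0), (10, 1)),
        )
        np.testing.assert_allclose(
            average_window(rec, (0, 10)), np.arange(20.0)
        )

    def test_arithmetic_series(self):
        # signal values 1..640 -> mean 320.5
        ts = np.arange(640) / 256.0
        values = np.tile(np.arange(1.0, 641.0)[:, None], (1, 20))
        rec = BandPowerRecording(timestamps=ts, values=values)
        np.testing.assert_allclose(average_window(rec, (0, 640)), 320.5)

    def test_ramp_mean_is_midpoint(self, ramp_recording):
        out = average_window(ramp_recording, (0, 513))
        np.testing.assert_allclose(out[0], ramp_recording.values[256, 0])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((64, 20))
        ts = np.arange(64) / 256.0
        a = average_window(BandPowerRecording(timestamps=ts, values=values), (0, 64))
        perm = rng.permutation(64)
        b = average_window(
            BandPowerRecording(timestamps=ts, values=values[perm]), (0, 64)
        )
        np.testing.assert_allclose(a, b)

    def test_empty_range_errors(self, ramp_recording):
        with pytest.raises(ValueError):
            average_window(ramp_recording, (5, 5))


class TestBuildSample:
    @pytest.mark.parametrize("S,W,expected_steps", [
        (2, 2, 1),
        (20, 2, 19),
        (2, 0.5, 7),
    ])
    def test_tensor_shapes(self, S, W, expected_steps):
        rec = _recording_of_rows(int((2 + S) * 256))
        cfg = SessionConfig(session_size=S, window_size=W, head_discard=2)
        sample = build_sample(rec, cfg)
        assert sample.tensor.shape == (expected_steps, 20)
        assert sample.label == "left"

    def test_unlabeled_rejected(self):
        rec = _recording_of_rows(1024, label="left")
        rec.label = "unlabeled"
        cfg = SessionConfig(session_size=2, window_size=2, head_discard=0)
        with pytest.raises(ValueError, match="labelled"):
            build_sample(rec, cfg)

    def test_deterministic(self, short_cfg):
        rec = generate_trial(short_cfg, "right", seed=1)
        cfg = SessionConfig(session_size=2, window_size=1, head_discard=2)
        a = build_sample(rec, cfg)
        b = build_sample(rec, cfg)
        np.testing.assert_array_equal(a.tensor, b.tensor)


class TestSegmentContinuous:
    def test_ten_samples_five_per_class(self, continuous_session):
        cfg = SessionConfig(session_size=2, window_size=2, head_discard=0)
        samples = segment_continuous(continuous_session, cfg)
        assert len(samples) == 10
        labels = [s.label for s in samples]
        assert labels.count("right") == 5 and labels.count("left") == 5
        assert labels[0] == "right"
        assert all(s.source_recording == samples[0].source_recording
                   for s in samples)

    def test_one_block_one_sample(self):
        rec = generate_continuous_session(
            SyntheticConfig(block_duration=60.0), seed=1
        )
        cfg = SessionConfig(session_size=2, window_size=2, head_discard=0)
        assert len(segment_continuous(rec, cfg)) == 1

    def test_seven_timesteps_for_half_second_windows(self, continuous_session):
        cfg = SessionConfig(session_size=2, window_size=0.5, head_discard=0)
        samples = segment_continuous(continuous_session, cfg)
        assert all(s.timesteps == 7 for s in samples)

    def test_short_blocks_error_lists_marks(self, continuous_session):
        cfg = SessionConfig(session_size=6.5, window_size=1, head_discard=0)
        with pytest.raises(ValueError, match="id="):
            segment_continuous(continuous_session, cfg)

    def test_no_markers_rejected(self, clean_trial):
        cfg = SessionConfig(session_size=2, window_size=2, head_discard=0)
        with pytest.raises(ValueError, match="markers"):
            segment_continuous(clean_trial, cfg)


class TestRejectNoisy:
    def _clean_batch(self, n, participant="P1", seed=0):
        cfg = SyntheticConfig(trial_duration=4.0)
        recs = generate_dataset(cfg, (n + 1) // 2, seed, participant)
        return recs[:n]

    def test_flatline_rejected(self):
        cfg = SyntheticConfig(trial_duration=4.0, p_flatline=1.0)
        rec = inject_artifacts(generate_trial(cfg, "left", 1), cfg, seed=1)
        kept, rejected = reject_noisy([rec], NoiseRules(min_recordings_per_subject=0))
        assert kept == []
        assert rejected[0][1].startswith("flatline:")

    def test_clean_recording_kept(self, clean_trial):
        kept, rejected = reject_noisy(
            [clean_trial], NoiseRules(min_recordings_per_subject=0)
        )
        assert len(kept) == 1 and rejected == []

    def test_outlier_heavy_recording_rejected(self):
        cfg = SyntheticConfig(trial_duration=4.0, p_outlier=0.05,
                              outlier_magnitude=20.0)
        rec = inject_artifacts(generate_trial(cfg, "left", 1), cfg, seed=1)
        kept, rejected = reject_noisy(
            [rec],
            NoiseRules(min_recordings_per_subject=0, outlier_z=8,
                       max_outlier_fraction=0.01),
        )
        assert kept == []
        assert rejected[0][1].startswith("outliers:")

    def test_unrepairable_rejected(self, clean_trial):
        rec = clean_trial.copy()
        rec.unrepairable = True
        kept, rejected = reject_noisy([rec], NoiseRules(min_recordings_per_subject=0))
        assert rejected[0][1] == "unrepairable"

    def test_subject_below_minimum_dropped(self):
        batch = self._clean_batch(13, "P_small") + self._clean_batch(14, "P_big", 99)
        kept, rejected = reject_noisy(batch, NoiseRules())
        assert all(r.participant_id == "P_big" for r in kept)
        assert len(kept) == 14
        small = [r for r, reason in rejected if reason == "subject_below_minimum"]
        assert len(small) == 13

    def test_empty_input(self):
        assert reject_noisy([], NoiseRules()) == ([], [])

    def test_rejection_monotone_in_thresholds(self):
        cfg = SyntheticConfig(trial_duration=4.0, p_outlier=0.02,
                              outlier_magnitude=12.0)
        recs = [
            inject_artifacts(generate_trial(cfg, "left", s), cfg, seed=s)
            for s in range(6)
        ]
        strict = NoiseRules(min_recordings_per_subject=0, outlier_z=6,
                            max_outlier_fraction=0.001)
        loose = NoiseRules(min_recordings_per_subject=0, outlier_z=10,
                           max_outlier_fraction=0.05)
        kept_strict, _ = reject_noisy(recs, strict)
        kept_loose, _ = reject_noisy(recs, loose)
        strict_ids = {id(r) for r in kept_strict}
        assert strict_ids <= {id(r) for r in kept_loose}
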