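"""Synthetic generator: shapes, labeling rule, determinism, rate calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from intakefuse import (
    ScoreStreamConfig,
    SimulationConfig,
    label_segments,
    simulate_detections,
    simulate_recording,
    simulate_score_streams,
)
from intakefuse.evaluation import iou


def _cfg(**kw):
    base = dict(duration_s=60.0, n_episodes=0, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateRecording:
    def test_sample_and_segment_counts(self):
        rec = simulate_recording(_cfg())
        assert rec.n_samples == 60 * 128 == 7680
        assert rec.segment_labels.size == 4

    def test_no_episodes_all_nonintake(self):
        rec = simulate_recording(_cfg())
        assert rec.segment_labels.sum() == 0
        assert rec.truth_episodes == []

    def test_half_overlap_rule_on_explicit_episode(self):
        # a 30-s episode spanning [15, 45) covers segments 1-2 fully
        rec = simulate_recording(_cfg(episodes=((15.0, 45.0),)))
        assert rec.segment_labels.tolist() == [0, 1, 1, 0]

    def test_exact_half_overlap_counts_as_intake(self):
        # episode [7.5, 22.5): both touched segments have exactly 50% overlap
        labels = label_segments([(7.5, 22.5)], duration_s=30.0)
        assert labels.tolist() == [1, 1]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration_s=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(sample_rate_hz=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(duration_s=60.0, episodes=((10.0, 90.0),))

    def test_deterministic_under_seed(self):
        cfg = _cfg(duration_s=120.0, n_episodes=1,
                   episode_duration_range_s=(30.0, 60.0),
                   inter_episode_gap_range_s=(10.0, 30.0), seed=5)
        a, b = simulate_recording(cfg), simulate_recording(cfg)
        assert np.array_equal(a.signal, b.signal)
        assert a.truth_episodes == b.truth_episodes

    def test_chew_band_energy_elevated_during_episodes(self):
        """Intake segments carry more 1-2.5 Hz power than non-intake ones."""
        cfg = _cfg(duration_s=600.0, n_episodes=2,
                   episode_duration_range_s=(90.0, 120.0),
                   inter_episode_gap_range_s=(60.0, 120.0), seed=3)
        rec = simulate_recording(cfg)
        assert 0 < rec.segment_labels.sum() < rec.segment_labels.size
        win = 15 * 128
        freqs = np.fft.rfftfreq(win, d=1 / 128)
        band = (freqs >= 1.0) & (freqs <= 2.5)
        power = []
        for i in range(rec.segment_labels.size):
            seg = rec.signal[i * win : (i + 1) * win]
            seg = seg - seg.mean(axis=0)
            spec = np.abs(np.fft.rfft(seg, axis=0)) ** 2
            power.append(spec[band].sum())
        power = np.asarray(power)
        lab = rec.segment_labels.astype(bool)
        assert power[lab].mean() > 2 * power[~lab].mean()

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_long_episodes_always_produce_intake_segments(self, seed):
        """Any truth episode lasting >= 15 s marks at least one segment."""
        cfg = _cfg(duration_s=600.0, n_episodes=3,
                   episode_duration_range_s=(15.0, 200.0),
                   inter_episode_gap_range_s=(20.0, 100.0), seed=seed)
        rec = simulate_recording(cfg)
        for start, end in rec.truth_episodes:
            if end - start < 15.0:
                continue
            n_seg = rec.segment_labels.size
            touched = [
                i for i in range(n_seg)
                if min((i + 1) * 15.0, end) - max(i * 15.0, start) > 0
            ]
            assert any(rec.segment_labels[i] == 1 for i in touched)


class TestScoreStreams:
    def test_lengths_match_labels(self):
        s = simulate_score_streams(np.zeros(100, dtype=int), ScoreStreamConfig(seed=1))
        assert len(s) == 100 and s.sf.size == s.sb.size == s.ss.size == 100

    def test_no_false_positives_when_fp_rate_zero(self):
        labels = np.zeros(500, dtype=int)
        cfg = ScoreStreamConfig(p_capture=1.0, fp_rate=0.0, missing_image_rate=0.0, seed=2)
        s = simulate_score_streams(labels, cfg)
        assert np.all(s.sf == 0.0) and np.all(s.sb == 0.0)

    def test_capture_when_p_capture_one(self):
        labels = np.ones(200, dtype=int)
        cfg = ScoreStreamConfig(p_capture=1.0, fp_rate=0.0, missing_image_rate=0.0, seed=2)
        s = simulate_score_streams(labels, cfg)
        assert np.all(s.sf > 0.0)

    def test_fp_rate_concentration(self):
        """At 10^4 non-intake segments the nonzero-Sf fraction sits at 0.2 +- 0.02."""
        labels = np.zeros(10_000, dtype=int)
        cfg = ScoreStreamConfig(fp_rate=0.2, missing_image_rate=0.0, seed=3)
        s = simulate_score_streams(labels, cfg)
        assert abs(np.mean(s.sf > 0) - 0.2) < 0.02

    def test_missing_images_zero_both_streams(self):
        labels = np.ones(2000, dtype=int)
        cfg = ScoreStreamConfig(p_capture=1.0, missing_image_rate=0.5, seed=4)
        s = simulate_score_streams(labels, cfg)
        assert s.missing.any()
        assert np.all(s.sf[s.missing] == 0.0) and np.all(s.sb[s.missing] == 0.0)
        assert np.all(s.ss > 0.0)  # the sensor stream never goes missing

    def test_deterministic_and_nonempty_required(self):
        cfg = ScoreStreamConfig(seed=9)
        labels = np.array([0, 1] * 50)
        a = simulate_score_streams(labels, cfg)
        b = simulate_score_streams(labels, cfg)
        for name in ("sf", "sb", "ss"):
            assert np.array_equal(getattr(a, name), getattr(b, name))
        with pytest.raises(ValueError):
            simulate_score_streams(np.array([], dtype=int), cfg)


class TestSimulateDetections:
    def test_perfect_detections_have_unit_iou(self):
        ds = simulate_detections(20, boxes_per_image=2, perturbation=0.0,
                                 spurious_rate=0.0, seed=0)
        for img in ds.images:
            assert len(ds.detections[img]) == len(ds.truth_boxes[img]) == 2
            for det, tb in zip(ds.detections[img], ds.truth_boxes[img]):
                assert iou(det[:4], tb[:4]) == pytest.approx(1.0)
                assert det[4] == tb[4]  # class preserved
                assert 0.0 <= det[5] <= 1.0

    def test_empty_and_negative(self):
        ds = simulate_detections(0, seed=1)
        assert ds.images == [] and ds.truth_boxes == {} and ds.detections == {}
        with pytest.raises(ValueError):
            simulate_detections(-1)

    def test_spurious_count_binomial_bound(self):
        ds = simulate_detections(1000, boxes_per_image=1, spurious_rate=0.5, seed=5)
        n_spurious = sum(len(ds.detections[i]) - 1 for i in ds.images)
        assert abs(n_spurious - 500) < 50

    def test_deterministic(self):
        a = simulate_detections(30, 2, 5.0, 0.3, seed=8)
        b = simulate_detections(30, 2, 5.0, 0.3, seed=8)
        assert a.detections == b.detections and a.truth_boxes == b.truth_boxes
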