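"""Metrics: confusion formulas, McNemar, IoU/AP/mAP, split utilities."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from intakefuse import (
    ConfusionCounts,
    DetectionEvalConfig,
    average_precision,
    holdout_split,
    iou,
    loso_split,
    mcnemar_test,
    mean_average_precision,
    segment_metrics,
    simulate_detections,
)
from intakefuse.evaluation import detection_set_tables


class TestSegmentMetrics:
    def test_worked_confusion_table(self):
        m = segment_metrics(ConfusionCounts(tp=8, fp=2, tn=88, fn=2))
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.96)
        assert m["f1"] == pytest.approx(0.8)

    def test_perfect_classifier(self):
        m = segment_metrics(ConfusionCounts(tp=5, fp=0, tn=10, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_zero_sensitivity(self):
        m = segment_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=3))
        assert m["sensitivity"] == 0.0

    def test_undefined_metric_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="precision"):
            m = segment_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=3))
        assert np.isnan(m["precision"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_f1_is_harmonic_mean(self, seed):
        rng = np.random.default_rng(seed)
        c = ConfusionCounts(*(int(v) for v in rng.integers(1, 500, size=4)))
        m = segment_metrics(c)
        harmonic = 2 * m["precision"] * m["sensitivity"] / (
            m["precision"] + m["sensitivity"]
        )
        assert m["f1"] == pytest.approx(harmonic)


class TestMcNemar:
    def test_symmetry(self):
        assert mcnemar_test(30, 4).chi_square == mcnemar_test(4, 30).chi_square

    def test_symmetric_discordance_not_rejected(self):
        r = mcnemar_test(5, 5)
        assert r.chi_square == pytest.approx(0.1)  # (0 - 1)^2 / 10
        assert not r.reject

    def test_no_discordant_pairs_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test(0, 0)
        with pytest.raises(ValueError):
            mcnemar_test(-1, 5)

    def test_alpha_controls_critical_value(self):
        assert mcnemar_test(20, 5, alpha=0.05).critical_value < \
            mcnemar_test(20, 5, alpha=0.01).critical_value


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 1, 1), (5, 5, 1, 1)) == 0.0

    def test_unit_cell_overlap(self):
        # 2x2 boxes offset by (1,1): intersection 1, union 7
        assert iou((0, 0, 2, 2), (1, 1, 2, 2)) == pytest.approx(1 / 7)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 2), (0, 0, 1, 1))


def brute_force_ap(detections, truths, iou_thr, score_thresholds):
    """Oracle AP: maximum-cardinality matching enumerated at each threshold."""
    n_truth = sum(len(b) for b in truths.values())
    points = []
    for tau in sorted(score_thresholds, reverse=True):
        kept = [d for d in detections if d[2] >= tau]
        if not kept:
            continue
        # best TP over all injective detection->truth assignments
        best_tp = 0
        truth_flat = [(img, j) for img, boxes in truths.items() for j in range(len(boxes))]
        for assign in itertools.product([None] + truth_flat, repeat=len(kept)):
            used = [a for a in assign if a is not None]
            if len(used) != len(set(used)):
                continue
            tp = 0
            ok = True
            for (img, box, _s), a in zip(kept, assign):
                if a is None:
                    continue
                timg, j = a
                if timg != img or iou(box, truths[img][j]) < iou_thr:
                    ok = False
                    break
                tp += 1
            if ok:
                best_tp = max(best_tp, tp)
        points.append((best_tp / n_truth, best_tp / len(kept)))
    if not points:
        return 0.0
    recalls = [0.0] + [r for r, _ in points]
    precisions = [points[0][1]] + [p for _, p in points]
    order = np.argsort(recalls, kind="stable")
    return float(np.trapezoid(np.asarray(precisions)[order], np.asarray(recalls)[order]))


class TestAveragePrecision:
    def test_single_perfect_detection(self):
        truths = {"a": [(0, 0, 10, 10)]}
        dets = [("a", (0, 0, 10, 10), 1.0)]
        for thr in (0.5, 0.75, 0.95):
            assert average_precision(dets, truths, thr) == pytest.approx(1.0)

    def test_low_iou_detection_scores_zero(self):
        truths = {"a": [(0, 0, 10, 10)]}
        dets = [("a", (8, 8, 10, 10), 0.9)]  # IoU ~ 0.026
        assert average_precision(dets, truths, 0.5) == 0.0

    def test_spurious_second_detection_lowers_ap(self):
        truths = {"a": [(0, 0, 10, 10)], "b": [(0, 0, 10, 10)]}
        dets = [("a", (0, 0, 10, 10), 0.9), ("b", (50, 50, 10, 10), 0.6)]
        ap = average_precision(dets, truths, 0.5)
        oracle = brute_force_ap(dets, truths, 0.5, DetectionEvalConfig().score_thresholds)
        assert ap == pytest.approx(oracle)
        assert 0.0 < ap < 1.0

    def test_no_truth_boxes_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(average_precision([], {}, 0.5))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle_on_small_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        truths = {"a": [tuple(rng.uniform(0, 50, 2)) + tuple(rng.uniform(5, 30, 2))
                        for _ in range(int(rng.integers(1, 3)))]}
        dets = [("a", tuple(rng.uniform(0, 50, 2)) + tuple(rng.uniform(5, 30, 2)),
                 float(rng.random())) for _ in range(int(rng.integers(0, 4)))]
        thr = float(rng.choice([0.3, 0.5, 0.75]))
        grid = DetectionEvalConfig().score_thresholds
        assert average_precision(dets, truths, thr, grid) == pytest.approx(
            brute_force_ap(dets, truths, thr, grid)
        )


class TestMeanAveragePrecision:
    def test_default_grids(self):
        cfg = DetectionEvalConfig()
        assert len(cfg.iou_thresholds) == 10
        assert cfg.iou_thresholds[0] == 0.5 and cfg.iou_thresholds[-1] == 0.95
        assert len(cfg.score_thresholds) == 11

    def test_perfect_synthetic_detections_give_100(self):
        ds = simulate_detections(40, boxes_per_image=2, perturbation=0.0,
                                 spurious_rate=0.0, seed=2)
        dets, truths = detection_set_tables(ds)
        result = mean_average_precision(dets, truths)
        assert result["overall"] == pytest.approx(100.0)
        assert result["food"] == pytest.approx(100.0)
        assert result["beverage"] == pytest.approx(100.0)

    def test_jitter_and_spurious_boxes_reduce_map(self):
        ds = simulate_detections(60, boxes_per_image=2, perturbation=25.0,
                                 spurious_rate=0.6, seed=3)
        dets, truths = detection_set_tables(ds)
        result = mean_average_precision(dets, truths)
        assert 0.0 < result["overall"] < 100.0

    def test_empty_class_set_rejected(self):
        with pytest.raises(ValueError):
            mean_average_precision({}, {})


class TestSplits:
    def test_loso_fold_structure(self):
        subjects = np.repeat(np.arange(5), 4)
        folds = list(loso_split(subjects))
        assert len(folds) == 5
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(20))  # partition
        for train, test in folds:
            assert set(subjects[train]).isdisjoint(set(subjects[test]))
            assert len(set(subjects[test])) == 1

    def test_loso_single_subject_rejected(self):
        with pytest.raises(ValueError):
            list(loso_split(np.zeros(5)))

    def test_holdout_sizes_and_cover(self):
        tr, va, te = holdout_split(100, seed=4)
        assert (len(tr), len(va), len(te)) == (80, 10, 10)
        assert sorted(np.concatenate([tr, va, te])) == list(range(100))

    def test_holdout_reproducible_and_validated(self):
        a = holdout_split(57, seed=9)
        b = holdout_split(57, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        with pytest.raises(ValueError):
            holdout_split(10, fractions=(0.5, 0.2, 0.2))
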