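"""Evaluation utilities: segment metrics, McNemar's test, mAP, data splits.

Segment- and episode-level classification is scored with sensitivity,
precision, accuracy and F1 from a confusion table. Paired classifiers are
compared with McNemar's continuity-corrected chi-square on discordant error
counts. Object detection is scored with COCO-style mAP@[.5,.95]: average
precision (area under the precision-recall curve sampled at confidence
thresholds 0, 0.1, ..., 1.0) averaged over IoU thresholds 0.50 to 0.95 in
steps of 0.05 and over classes. Split utilities implement
leave-one-subject-out cross-validation and the 80/10/10 random holdout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class McNemarResult:
    e01: int
    e10: int
    chi_square: float
    alpha: float
    critical_value: float
    reject: bool


@dataclass(frozen=True)
class DetectionEvalConfig:
    """IoU and confidence-score threshold grids for mAP@[.5,.95]."""

    iou_thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))
    score_thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.001, 0.1), 1))

    def __post_init__(self) -> None:
        for grid in (self.iou_thresholds, self.score_thresholds):
            arr = np.asarray(grid)
            if np.any(np.diff(arr) <= 0) or arr.min() < 0 or arr.max() > 1:
                raise ValueError("thresholds must be sorted and within [0, 1]")


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def segment_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, precision, accuracy and F1 from a confusion table.

    Sensitivity = TP/(TP+FN), Precision = TP/(TP+FP),
    Accuracy = (TP+TN)/total, F1 = 2TP/(2TP+FN+FP). Zero denominators give
    NaN with a warning rather than a silently inflating 0.
    """
    total = c.tp + c.fp + c.tn + c.fn
    if total == 0:
        raise ValueError("empty confusion table")
    return {
        "sensitivity": _safe_div(c.tp, c.tp + c.fn, "sensitivity"),
        "precision": _safe_div(c.tp, c.tp + c.fp, "precision"),
        "accuracy": (c.tp + c.tn) / total,
        "f1": _safe_div(2 * c.tp, 2 * c.tp + c.fn + c.fp, "F1"),
    }


def mcnemar_test(e01: int, e10: int, alpha: float = 0.01) -> McNemarResult:
    """Continuity-corrected McNemar's test on discordant error counts.

    chi^2 = (|e01 - e10| - 1)^2 / (e01 + e10), compared against the upper
    alpha quantile of chi-square with 1 degree of freedom. e01 counts cases
    misclassified by classifier 1 but not 2; e10 the reverse.
    """
    if e01 < 0 or e10 < 0:
        raise ValueError("discordant counts must be non-negative")
    if e01 + e10 == 0:
        raise ValueError("McNemar's test undefined: no discordant pairs")
    chi_square = (abs(e01 - e10) - 1) ** 2 / (e01 + e10)
    critical = float(stats.chi2.ppf(1.0 - alpha, df=1))
    return McNemarResult(
        e01=e01,
        e10=e10,
        chi_square=chi_square,
        alpha=alpha,
        critical_value=critical,
        reject=chi_square > critical,
    )


def iou(box_a: Sequence[float], box_b: Sequence[float]) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = box_a[:4]
    bx, by, bw, bh = box_b[:4]
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("boxes must have positive width and height")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


def _match_at_threshold(
    detections: Sequence[tuple[str, Sequence[float], float]],
    truths: Mapping[str, Sequence[Sequence[float]]],
    score_threshold: float,
    iou_threshold: float,
) -> tuple[int, int]:
    """Greedy matching (descending score, one truth per detection).

    detections: (image_id, box, score) tuples; truths: image_id -> boxes.
    Returns (TP, number of detections kept at the score threshold).
    """
    kept = [d for d in detections if d[2] >= score_threshold]
    kept.sort(key=lambda d: -d[2])
    used: dict[str, list[bool]] = {img: [False] * len(b) for img, b in truths.items()}
    tp = 0
    for img, box, _score in kept:
        boxes = truths.get(img, ())
        best_j, best_iou = -1, iou_threshold
        for j, tb in enumerate(boxes):
            if used[img][j]:
                continue
            ov = iou(box, tb)
            if ov >= best_iou:
                best_j, best_iou = j, ov
        if best_j >= 0:
            used[img][best_j] = True
            tp += 1
    return tp, len(kept)


def average_precision(
    detections: Sequence[tuple[str, Sequence[float], float]],
    truths: Mapping[str, Sequence[Sequence[float]]],
    iou_threshold: float,
    score_thresholds: Sequence[float] | None = None,
) -> float:
    """AP at one IoU threshold: area under the sampled precision-recall curve.

    Precision and recall are computed at each confidence threshold of the
    grid (default 0 to 1 step 0.1); detections above the threshold are
    greedily matched to unmatched truth boxes of the same image requiring
    IoU >= ``iou_threshold``. The PR points (ordered by ascending recall) are
    augmented with (recall=0, precision of the first point) and integrated by
    the trapezoidal rule.
    """
    n_truth = sum(len(b) for b in truths.values())
    if n_truth == 0:
        warnings.warn("no ground-truth boxes: AP undefined", stacklevel=2)
        return float("nan")
    if score_thresholds is None:
        score_thresholds = DetectionEvalConfig().score_thresholds
    points: list[tuple[float, float]] = []  # (recall, precision), descending threshold
    for tau in sorted(score_thresholds, reverse=True):
        tp, n_det = _match_at_threshold(detections, truths, tau, iou_threshold)
        if n_det == 0:
            continue  # precision undefined at this threshold
        points.append((tp / n_truth, tp / n_det))
    if not points:
        return 0.0
    recalls = [0.0] + [r for r, _ in points]
    precisions = [points[0][1]] + [p for _, p in points]
    order = np.argsort(recalls, kind="stable")
    r = np.asarray(recalls)[order]
    p = np.asarray(precisions)[order]
    return float(np.trapezoid(p, r))


def mean_average_precision(
    detections_by_class: Mapping[str, Sequence[tuple[str, Sequence[float], float]]],
    truths_by_class: Mapping[str, Mapping[str, Sequence[Sequence[float]]]],
    config: DetectionEvalConfig = DetectionEvalConfig(),
) -> dict[str, float]:
    """mAP@[.5,.95] per class and overall, on the 0-100 scale.

    Per class, AP is averaged over the 10 IoU thresholds; the overall score
    is the mean over classes.
    """
    if not truths_by_class:
        raise ValueError("no classes to evaluate")
    result: dict[str, float] = {}
    per_class = []
    for cls, truths in truths_by_class.items():
        aps = [
            average_precision(
                detections_by_class.get(cls, ()), truths, thr, config.score_thresholds
            )
            for thr in config.iou_thresholds
        ]
        m = 100.0 * float(np.mean(aps))
        result[cls] = m
        per_class.append(m)
    result["overall"] = float(np.mean(per_class))
    return result


def detection_set_tables(detection_set) -> tuple[dict, dict]:
    """Reshape a SyntheticDetectionSet into per-class mAP inputs."""
    dets: dict[str, list] = {}
    truths: dict[str, dict] = {}
    for img in detection_set.images:
        for x, y, w, h, cls in detection_set.truth_boxes[img]:
            truths.setdefault(cls, {}).setdefault(img, []).append((x, y, w, h))
        for x, y, w, h, cls, score in detection_set.detections[img]:
            dets.setdefault(cls, []).append((img, (x, y, w, h), score))
    # every image must be present in each class's truth map so spurious
    # detections on truth-free images count as false positives
    for cls in truths:
        for img in detection_set.images:
            truths[cls].setdefault(img, [])
    return dets, truths


def loso_split(subject_ids: Sequence) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-subject-out folds: one fold per subject, test = that subject.

    Yields (train_indices, test_indices) per unique subject in sorted order;
    the test folds partition the records.
    """
    ids = np.asarray(subject_ids)
    subjects = np.unique(ids)
    if subjects.size < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    for subject in subjects:
        test = np.flatnonzero(ids == subject)
        train = np.flatnonzero(ids != subject)
        yield train, test


def holdout_split(
    n_records: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random 80/10/10 train/validation/test index split, seeded.

    The three parts are disjoint, cover all records, and have sizes within
    one record of the exact fractions.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n_records)
    n_train = int(round(fractions[0] * n_records))
    n_val = int(round((fractions[0] + fractions[1]) * n_records)) - n_train
    return idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :]
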