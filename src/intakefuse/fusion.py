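"""Score-level fusion of image- and sensor-based intake evidence.

Each 15-s segment carries three confidence scores: Sf (food object, the
maximum detector confidence over food boxes in the segment's image), Sb
(beverage object, analogous) and Ss (sensor CNN probability of intake).
Scores from the current segment and the ``n`` preceding segments form the
predictor vector [Sf(t)..Sf(t-n), Sb(t)..Sb(t-n), Ss(t)..Ss(t-n)] of length
3(n+1), classified by a cost-sensitive random forest (30 trees, at most 1000
splits each, misclassification cost [0 1; 2 0] doubling the penalty on missed
intake). The lag n is chosen by grid search over n = 0..4 on a validation
split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

STREAMS = ("sf", "sb", "ss")


@dataclass
class ConfidenceSeries:
    """Aligned per-segment confidence score streams.

    All arrays share one length (one entry per 15-s segment). ``label`` is
    the ground-truth intake label where known; ``missing`` flags segments
    whose image was not captured (their Sf = Sb = 0 by convention).
    """

    t_start_s: np.ndarray
    sf: np.ndarray
    sb: np.ndarray
    ss: np.ndarray
    label: np.ndarray | None = None
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_start_s = np.asarray(self.t_start_s, dtype=float)
        self.sf = np.asarray(self.sf, dtype=float)
        self.sb = np.asarray(self.sb, dtype=float)
        self.ss = np.asarray(self.ss, dtype=float)
        n = len(self.t_start_s)
        for name in ("sf", "sb", "ss"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n}")
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"{name} scores must lie in [0, 1]")
        if n > 1 and np.any(np.diff(self.t_start_s) <= 0):
            raise ValueError("segment start times must be strictly increasing")
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=int)
            if len(self.label) != n:
                raise ValueError("label length mismatch")
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if len(self.missing) != n:
                raise ValueError("missing-flag length mismatch")

    def __len__(self) -> int:
        return len(self.t_start_s)

    def stream(self, name: str) -> np.ndarray:
        if name not in STREAMS:
            raise KeyError(f"unknown stream {name!r}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "segment_index": np.arange(len(self)),
                "t_start_s": self.t_start_s,
                "Sf": self.sf,
                "Sb": self.sb,
                "Ss": self.ss,
            }
        )
        if self.label is not None:
            df["label"] = self.label
        if self.missing is not None:
            df["missing"] = self.missing.astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConfidenceSeries":
        return cls(
            t_start_s=df["t_start_s"].to_numpy(),
            sf=df["Sf"].to_numpy(),
            sb=df["Sb"].to_numpy(),
            ss=df["Ss"].to_numpy(),
            label=df["label"].to_numpy() if "label" in df else None,
            missing=df["missing"].to_numpy(dtype=bool) if "missing" in df else None,
        )


@dataclass(frozen=True)
class FusionParams:
    """Random-forest fusion hyperparameters.

    ``max_splits_per_tree`` bounds branch nodes per tree (realized as a
    max_leaf_nodes cap: a binary tree with k leaves has k - 1 splits);
    ``intake_cost`` is the misclassification cost on the intake class
    relative to unit cost on non-intake, i.e. the cost matrix [0 1; c 0].
    """

    n_trees: int = 30
    max_splits_per_tree: int = 1000
    intake_cost: float = 2.0
    seed: int = 0


@dataclass
class FusionModel:
    forest: RandomForestClassifier
    n: int
    params: FusionParams
    streams: tuple[str, ...] = STREAMS


def extract_image_scores(
    detections_per_segment: Sequence[Iterable[tuple[str, float]] | None],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse per-image object detections to (Sf, Sb) per segment.

    Each element is the detection list of the image captured in that segment
    (pairs of class name in {"food", "beverage"} and confidence score), or
    None for a missing image. If multiple objects of a class were detected,
    the highest confidence score is counted; absence of a class scores 0.

    Returns (sf, sb, missing_flags).
    """
    n = len(detections_per_segment)
    sf = np.zeros(n)
    sb = np.zeros(n)
    missing = np.zeros(n, dtype=bool)
    for i, dets in enumerate(detections_per_segment):
        if dets is None:
            missing[i] = True
            continue
        for cls, score in dets:
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"confidence score {score} outside [0, 1]")
            if cls == "food":
                sf[i] = max(sf[i], score)
            elif cls == "beverage":
                sb[i] = max(sb[i], score)
            else:
                raise ValueError(f"unknown object class {cls!r}")
    return sf, sb, missing


def build_predictor_vectors(
    series: ConfidenceSeries,
    n: int,
    streams: Sequence[str] = STREAMS,
) -> np.ndarray:
    """Stack current and n lagged scores into one row per segment.

    Row ordering is [Sf(t)..Sf(t-n), Sb(t)..Sb(t-n), Ss(t)..Ss(t-n)]
    (restricted to ``streams``); lags reaching before the first segment are
    zero-padded — zero meaning "no evidence", the same convention as a
    missing detection.
    """
    if n < 0:
        raise ValueError("lag count n must be >= 0")
    if len(series) == 0:
        raise ValueError("empty confidence series")
    cols = []
    for name in streams:
        s = series.stream(name)
        for lag in range(n + 1):
            lagged = np.zeros(len(s))
            if lag < len(s):
                lagged[lag:] = s[: len(s) - lag]
            cols.append(lagged)
    return np.column_stack(cols)


def train_fusion(
    vectors: np.ndarray,
    labels: np.ndarray,
    params: FusionParams = FusionParams(),
    *,
    n: int | None = None,
    streams: Sequence[str] = STREAMS,
) -> FusionModel:
    """Fit the cost-sensitive random forest on predictor vectors."""
    X = np.asarray(vectors, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("vectors and labels must align")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    if n is None:
        n = X.shape[1] // len(streams) - 1
    forest = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_leaf_nodes=params.max_splits_per_tree + 1,
        class_weight={0: 1.0, 1: params.intake_cost},
        random_state=params.seed,
    )
    forest.fit(X, y)
    return FusionModel(forest=forest, n=n, params=params, streams=tuple(streams))


def predict_fused(model: FusionModel, vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment intake label and fused score (forest vote fraction)."""
    X = np.asarray(vectors, dtype=float)
    expected = len(model.streams) * (model.n + 1)
    if X.ndim != 2 or X.shape[1] != expected:
        raise ValueError(
            f"predictor width {X.shape[1] if X.ndim == 2 else '?'} != 3(n+1) = {expected}"
        )
    votes = np.stack([tree.predict(X) for tree in model.forest.estimators_])
    scores = votes.mean(axis=0)
    labels = model.forest.predict(X)
    return labels.astype(int), scores


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    denom = 2 * tp + fn + fp
    return 2 * tp / denom if denom else float("nan")


def grid_search_n(
    train_series: ConfidenceSeries,
    val_series: ConfidenceSeries,
    n_range: Sequence[int] = range(0, 5),
    params: FusionParams = FusionParams(),
    streams: Sequence[str] = STREAMS,
) -> tuple[int, dict[int, float]]:
    """Select the temporal lag n by validation F1 over n = 0..4.

    One fusion model is trained per candidate n on the training series and
    scored on the validation series; ties break toward the smallest n
    (the cheapest model). Returns (best_n, per-n F1 scores).
    """
    n_range = list(n_range)
    if not n_range:
        raise ValueError("empty n_range")
    if train_series.label is None or val_series.label is None:
        raise ValueError("grid search requires labeled series")
    scores: dict[int, float] = {}
    best_n, best_score = None, -np.inf
    for n in sorted(n_range):
        model = train_fusion(
            build_predictor_vectors(train_series, n, streams),
            train_series.label,
            params,
            n=n,
            streams=streams,
        )
        pred, _ = predict_fused(model, build_predictor_vectors(val_series, n, streams))
        f1 = _f1(val_series.label, pred)
        scores[n] = f1
        if np.isfinite(f1) and f1 > best_score:
            best_n, best_score = n, f1
    if best_n is None:
        best_n = min(n_range)
        logger.warning("no finite validation F1; falling back to n=%d", best_n)
    return best_n, scores
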