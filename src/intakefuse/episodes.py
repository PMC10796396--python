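"""Aggregation of per-segment intake decisions into eating events and episodes.

A maximal run of consecutive intake-classified 15-s segments is one eating
event; events separated by less than 15 minutes are merged into one eating
episode (a meal or snack bout). Episode-level evaluation matches predicted
episodes one-to-one against ground-truth episodes by temporal overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_MERGE_GAP_MIN = 15.0


@dataclass(frozen=True)
class EatingEvent:
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"event end {self.end_s} must exceed start {self.start_s}")


@dataclass(frozen=True)
class EatingEpisode:
    start_s: float
    end_s: float
    events: tuple[EatingEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("episode end must exceed start")


@dataclass(frozen=True)
class EpisodeConfusion:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def segments_to_events(
    labels: Sequence[int],
    segment_starts_s: Sequence[float] | None = None,
    window_s: float = 15.0,
) -> list[EatingEvent]:
    """Merge maximal runs of intake segments into events.

    An event spans from the start of its first segment to the end
    (start + window) of its last.
    """
    labels = np.asarray(labels, dtype=int)
    if segment_starts_s is None:
        starts = np.arange(labels.size) * window_s
    else:
        starts = np.asarray(segment_starts_s, dtype=float)
        if starts.size != labels.size:
            raise ValueError("labels and segment starts must align")
    events: list[EatingEvent] = []
    run_start: float | None = None
    for i, lab in enumerate(labels):
        if lab == 1 and run_start is None:
            run_start = float(starts[i])
        if lab == 0 and run_start is not None:
            events.append(EatingEvent(run_start, float(starts[i - 1]) + window_s))
            run_start = None
    if run_start is not None:
        events.append(EatingEvent(run_start, float(starts[-1]) + window_s))
    return events


def merge_events_to_episodes(
    events: Sequence[EatingEvent],
    gap_min: float = DEFAULT_MERGE_GAP_MIN,
) -> list[EatingEpisode]:
    """Combine events with inter-event interval < ``gap_min`` minutes.

    The bound is strict: a gap of exactly ``gap_min`` minutes starts a new
    episode. Unsorted input is sorted internally with a warning.
    """
    if not events:
        return []
    evs = list(events)
    if any(evs[i].start_s > evs[i + 1].start_s for i in range(len(evs) - 1)):
        logger.warning("events were not sorted by start time; sorting")
        evs = sorted(evs, key=lambda e: e.start_s)
    gap_s = gap_min * 60.0
    episodes: list[EatingEpisode] = []
    cluster = [evs[0]]
    cluster_end = evs[0].end_s
    for ev in evs[1:]:
        # compare against the latest end seen in the cluster, not the last
        # event's end: events may nest when predictions overlap
        if ev.start_s - cluster_end < gap_s:
            cluster.append(ev)
            cluster_end = max(cluster_end, ev.end_s)
        else:
            episodes.append(_episode_from(cluster))
            cluster = [ev]
            cluster_end = ev.end_s
    episodes.append(_episode_from(cluster))
    return episodes


def _episode_from(cluster: list[EatingEvent]) -> EatingEpisode:
    return EatingEpisode(
        start_s=min(e.start_s for e in cluster),
        end_s=max(e.end_s for e in cluster),
        events=tuple(cluster),
    )


def _check_disjoint(eps: Sequence[EatingEpisode], name: str) -> None:
    for a, b in zip(eps, eps[1:]):
        if b.start_s < a.end_s:
            raise ValueError(f"{name} episodes overlap: {a} and {b}")


def match_episodes(
    predicted: Sequence[EatingEpisode],
    truth: Sequence[EatingEpisode],
    min_overlap_s: float = 1.0,
) -> EpisodeConfusion:
    """Greedy one-to-one temporal matching of predicted vs truth episodes.

    Predicted episodes are scanned in time order; each is matched to the
    still-unmatched truth episode with the greatest temporal overlap,
    provided that overlap is at least ``min_overlap_s`` seconds. Matched
    predictions are TP, unmatched predictions FP, unmatched truths FN.
    """
    pred = sorted(predicted, key=lambda e: e.start_s)
    tru = sorted(truth, key=lambda e: e.start_s)
    _check_disjoint(pred, "predicted")
    _check_disjoint(tru, "truth")
    matched = [False] * len(tru)
    tp = 0
    for p in pred:
        best_j, best_ov = -1, 0.0
        for j, tr in enumerate(tru):
            if matched[j]:
                continue
            ov = min(p.end_s, tr.end_s) - max(p.start_s, tr.start_s)
            if ov >= min_overlap_s and ov > best_ov:
                best_j, best_ov = j, ov
        if best_j >= 0:
            matched[best_j] = True
            tp += 1
    fp = len(pred) - tp
    fn = len(tru) - tp
    return EpisodeConfusion(tp=tp, fp=fp, fn=fn)
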