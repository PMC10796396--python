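"""Synthetic free-living recordings, detector score streams and box fixtures.

The study data this pipeline targets (wrist/temporalis accelerometry at
128 Hz plus one egocentric image every 15 s) is not publicly available, so
this module generates inputs with the statistical structure the pipeline
assumes:

* tri-axial accelerometer recordings — a slowly varying gravity/posture
  baseline plus Gaussian sensor noise, transient motion artifacts, and
  amplitude-modulated chewing-band oscillations (1-2.5 Hz) during eating
  episodes;
* per-segment detector confidence streams correlated with the eating state,
  with configurable capture probability and false-positive rate (emulating a
  wearable camera seeing food that is not being consumed);
* bounding-box detection fixtures for the mAP evaluation code.

All draws flow from one seeded generator per call; identical config + seed
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fusion import ConfidenceSeries
from .scalogram import DEFAULT_WINDOW_S

FOOD, BEVERAGE = "food", "beverage"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic accelerometer recording.

    Amplitudes are in g-units. ``chew_amplitude`` = 0.15 g against
    ``noise_amplitude`` = 0.05 g gives a clearly band-limited but not
    noise-free chewing signature; ``motion_artifact_rate_per_hour`` sprinkles
    short non-eating movement bursts over the whole recording. Episodes are
    placed sequentially with durations and inter-episode gaps drawn from the
    configured ranges, or taken verbatim from ``episodes`` when given.

    Defaults emulate a two-hour free-living stretch: meal/snack episodes of
    5-15 minutes separated by 16-40 minute gaps (so distinct meals survive
    the < 15-min episode-merge rule). Classifier-training configs typically
    override toward shorter, denser recordings.
    """

    duration_s: float = 7200.0
    sample_rate_hz: float = 128.0
    n_episodes: int = 3
    episode_duration_range_s: tuple[float, float] = (300.0, 900.0)
    inter_episode_gap_range_s: tuple[float, float] = (960.0, 2400.0)
    chew_freq_range_hz: tuple[float, float] = (1.0, 2.5)
    chew_amplitude: float = 0.15
    noise_amplitude: float = 0.05
    motion_artifact_rate_per_hour: float = 20.0
    seed: int = 0
    episodes: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.chew_amplitude < 0 or self.noise_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.episodes is not None:
            eps = tuple((float(a), float(b)) for a, b in self.episodes)
            last = 0.0
            for a, b in eps:
                if not (0.0 <= a < b <= self.duration_s):
                    raise ValueError(f"episode ({a}, {b}) outside [0, duration]")
                if a < last:
                    raise ValueError("episodes must be sorted and non-overlapping")
                last = b
            object.__setattr__(self, "episodes", eps)


@dataclass
class LabeledRecording:
    """Tri-axial signal with per-segment intake labels and truth episodes."""

    signal: np.ndarray  # (n_samples, 3), g-units
    sample_rate_hz: float
    segment_labels: np.ndarray  # per-15-s-segment binary
    truth_episodes: list[tuple[float, float]]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass(frozen=True)
class ScoreStreamConfig:
    """Detector/sensor score-stream emulation parameters.

    ``p_capture`` — probability that the image of an intake segment actually
    shows a detectable food (resp. beverage) object; ``fp_rate`` — probability
    that a non-intake segment's image yields a spurious food/beverage score;
    ``missing_image_rate`` — probability the camera produced no usable image.
    Positive/negative scores are Beta draws (defaults Beta(5,2) vs Beta(2,5)),
    overlapping enough that neither stream is noiseless.
    """

    p_capture: float = 0.7
    fp_rate: float = 0.2
    score_dist_pos: tuple[float, float] = (5.0, 2.0)
    score_dist_neg: tuple[float, float] = (2.0, 5.0)
    missing_image_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_capture", "fp_rate", "missing_image_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SyntheticDetectionSet:
    """Scored bounding boxes plus ground truth for mAP evaluation.

    Boxes are (x, y, w, h) in pixels on a nominal 640 x 480 canvas;
    detections additionally carry a class name and a confidence score.
    """

    images: list[str]
    truth_boxes: dict[str, list[tuple[float, float, float, float, str]]]
    detections: dict[str, list[tuple[float, float, float, float, str, float]]]


def label_segments(
    episodes: Sequence[tuple[float, float]],
    duration_s: float,
    window_s: float = DEFAULT_WINDOW_S,
    min_overlap: float = 0.5,
) -> np.ndarray:
    """Binary per-window labels: intake iff >= 50% of the window overlaps an episode."""
    n_seg = int(duration_s // window_s)
    labels = np.zeros(n_seg, dtype=int)
    for i in range(n_seg):
        a, b = i * window_s, (i + 1) * window_s
        overlap = sum(max(0.0, min(b, e) - max(a, s)) for s, e in episodes)
        if overlap / window_s >= min_overlap:
            labels[i] = 1
    return labels


def _place_episodes(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    if config.episodes is not None:
        return list(config.episodes)
    episodes: list[tuple[float, float]] = []
    gap_lo, gap_hi = config.inter_episode_gap_range_s
    dur_lo, dur_hi = config.episode_duration_range_s
    t = rng.uniform(0.0, gap_hi)
    for _ in range(config.n_episodes):
        start = t
        end = start + rng.uniform(dur_lo, dur_hi)
        if start >= config.duration_s:
            break
        end = min(end, config.duration_s)
        if end > start:
            episodes.append((start, end))
        t = end + rng.uniform(gap_lo, gap_hi)
    return episodes


def simulate_recording(config: SimulationConfig) -> LabeledRecording:
    """Generate one labeled tri-axial accelerometer recording.

    Signal model per axis: a gravity/posture baseline that drifts on a
    ~minute timescale, white Gaussian sensor noise, occasional smooth motion
    bumps, and — inside each eating episode — a chewing oscillation: a
    sinusoid at an episode-specific frequency from ``chew_freq_range_hz``
    with slow amplitude modulation and mild frequency jitter, projected onto
    a random orientation (chewing is band-limited, not axis-aligned).
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    episodes = _place_episodes(config, rng)

    # posture baseline: unit gravity slowly tilting between random orientations
    base_freqs = rng.uniform(0.002, 0.01, size=3)
    base_phase = rng.uniform(0, 2 * np.pi, size=3)
    signal = np.empty((n, 3))
    signal[:, 0] = 0.15 * np.sin(2 * np.pi * base_freqs[0] * t + base_phase[0])
    signal[:, 1] = 0.15 * np.sin(2 * np.pi * base_freqs[1] * t + base_phase[1])
    signal[:, 2] = 1.0 + 0.1 * np.sin(2 * np.pi * base_freqs[2] * t + base_phase[2])
    signal += rng.normal(0.0, config.noise_amplitude, size=(n, 3))

    # transient motion artifacts (head turns, walking bouts): smooth bumps
    n_art = rng.poisson(config.motion_artifact_rate_per_hour * config.duration_s / 3600.0)
    for _ in range(n_art):
        center = rng.uniform(0, config.duration_s)
        width = rng.uniform(0.5, 2.0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        amp = rng.uniform(0.2, 0.5)
        envelope = amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        signal += envelope[:, None] * direction[None, :]

    # chewing bursts during episodes
    for start, end in episodes:
        f0 = rng.uniform(*config.chew_freq_range_hz)
        phase = rng.uniform(0, 2 * np.pi)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        mod_f = rng.uniform(0.05, 0.15)  # bite/pause rhythm
        mask = (t >= start) & (t < end)
        tt = t[mask]
        ramp = np.minimum(1.0, np.minimum(tt - start, end - tt))  # 1-s edge ramps
        envelope = config.chew_amplitude * ramp * (0.75 + 0.25 * np.sin(2 * np.pi * mod_f * tt))
        inst_freq = f0 * (1.0 + 0.05 * np.sin(2 * np.pi * 0.2 * tt + phase))
        chew = envelope * np.sin(2 * np.pi * np.cumsum(inst_freq) / fs)
        signal[mask] += chew[:, None] * direction[None, :]

    labels = label_segments(episodes, config.duration_s)
    return LabeledRecording(
        signal=signal,
        sample_rate_hz=fs,
        segment_labels=labels,
        truth_episodes=episodes,
    )


def simulate_score_streams(
    labels: np.ndarray,
    config: ScoreStreamConfig = ScoreStreamConfig(),
    window_s: float = DEFAULT_WINDOW_S,
) -> ConfidenceSeries:
    """Emulate per-segment detector and sensor confidence streams.

    For intake segments Sf (and, independently, Sb) is a positive-class Beta
    draw with probability ``p_capture``, else 0; for non-intake segments a
    negative-class draw with probability ``fp_rate``, else 0. Segments whose
    image is flagged missing get Sf = Sb = 0. Ss is always present (the
    sensor runs continuously): a positive draw for intake segments, negative
    otherwise.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    rng = np.random.default_rng(config.seed)
    n = labels.size
    a_pos, b_pos = config.score_dist_pos
    a_neg, b_neg = config.score_dist_neg

    def image_stream() -> np.ndarray:
        present = np.where(
            labels == 1,
            rng.random(n) < config.p_capture,
            rng.random(n) < config.fp_rate,
        )
        draws = np.where(
            labels == 1,
            rng.beta(a_pos, b_pos, size=n),
            rng.beta(a_neg, b_neg, size=n),
        )
        return np.where(present, draws, 0.0)

    sf = image_stream()
    sb = image_stream()
    ss = np.where(
        labels == 1,
        rng.beta(a_pos, b_pos, size=n),
        rng.beta(a_neg, b_neg, size=n),
    )
    missing = rng.random(n) < config.missing_image_rate
    sf[missing] = 0.0
    sb[missing] = 0.0
    return ConfidenceSeries(
        t_start_s=np.arange(n) * window_s,
        sf=sf,
        sb=sb,
        ss=ss,
        label=labels,
        missing=missing,
    )


def simulate_detections(
    n_images: int,
    boxes_per_image: int = 1,
    perturbation: float = 0.0,
    spurious_rate: float = 0.0,
    seed: int = 0,
    canvas: tuple[int, int] = (640, 480),
) -> SyntheticDetectionSet:
    """Bounding-box fixture: jittered copies of truth boxes plus spurious boxes.

    Each truth box yields one detection whose corner and size are offset by
    at most ``perturbation`` pixels, scored from a high Beta(8, 2); with
    probability ``spurious_rate`` an image additionally gains one random
    low-scored (Beta(2, 8)) spurious box.
    """
    if n_images < 0 or boxes_per_image < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    W, H = canvas
    images = [f"img_{i:05d}" for i in range(n_images)]
    truth: dict[str, list] = {}
    dets: dict[str, list] = {}
    for img in images:
        boxes = []
        detections = []
        for _ in range(boxes_per_image):
            w = rng.uniform(40, 160)
            h = rng.uniform(40, 160)
            x = rng.uniform(0, W - w)
            y = rng.uniform(0, H - h)
            cls = FOOD if rng.random() < 0.5 else BEVERAGE
            boxes.append((x, y, w, h, cls))
            jitter = rng.uniform(-perturbation, perturbation, size=4)
            dw = max(1.0, w + jitter[2])
            dh = max(1.0, h + jitter[3])
            detections.append(
                (x + jitter[0], y + jitter[1], dw, dh, cls, float(rng.beta(8, 2)))
            )
        if rng.random() < spurious_rate:
            w = rng.uniform(40, 160)
            h = rng.uniform(40, 160)
            cls = FOOD if rng.random() < 0.5 else BEVERAGE
            detections.append(
                (
                    rng.uniform(0, W - w),
                    rng.uniform(0, H - h),
                    w,
                    h,
                    cls,
                    float(rng.beta(2, 8)),
                )
            )
        truth[img] = boxes
        dets[img] = detections
    return SyntheticDetectionSet(images=images, truth_boxes=truth, detections=dets)
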