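"""Plain-text file formats for every pipeline artifact.

Recordings are CSV (time_s, ax, ay, az) with a JSON label/episode sidecar;
score streams are CSV (segment_index, t_start_s, Sf, Sb, Ss[, label,
missing]); detections and episodes are JSON; scalograms are 8-bit grayscale
PNG with a JSON sidecar. All schemas are documented so externally produced
detector outputs can be substituted for the synthetic streams.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .episodes import EatingEpisode, EatingEvent
from .fusion import ConfidenceSeries
from .scalogram import ScalogramImage
from .synthetic import LabeledRecording, SyntheticDetectionSet


def write_recording(recording: LabeledRecording, csv_path: str | Path,
                    labels_path: str | Path | None = None) -> None:
    csv_path = Path(csv_path)
    t = np.arange(recording.n_samples) / recording.sample_rate_hz
    pd.DataFrame(
        {
            "time_s": t,
            "ax": recording.signal[:, 0],
            "ay": recording.signal[:, 1],
            "az": recording.signal[:, 2],
        }
    ).to_csv(csv_path, index=False, float_format="%.6f")
    if labels_path is None:
        labels_path = csv_path.with_suffix(".labels.json")
    Path(labels_path).write_text(
        json.dumps(
            {
                "sample_rate_hz": recording.sample_rate_hz,
                "segment_labels": recording.segment_labels.tolist(),
                "truth_episodes": [list(e) for e in recording.truth_episodes],
            },
            indent=2,
        )
    )


def read_recording(csv_path: str | Path,
                   labels_path: str | Path | None = None) -> LabeledRecording:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    signal = df[["ax", "ay", "az"]].to_numpy()
    if labels_path is None:
        labels_path = csv_path.with_suffix(".labels.json")
    meta = json.loads(Path(labels_path).read_text())
    return LabeledRecording(
        signal=signal,
        sample_rate_hz=float(meta["sample_rate_hz"]),
        segment_labels=np.asarray(meta["segment_labels"], dtype=int),
        truth_episodes=[tuple(e) for e in meta["truth_episodes"]],
    )


def write_scores(series: ConfidenceSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_scores(path: str | Path) -> ConfidenceSeries:
    return ConfidenceSeries.from_frame(pd.read_csv(path))


def write_detections(ds: SyntheticDetectionSet, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "images": ds.images,
                "truth_boxes": {k: [list(b) for b in v] for k, v in ds.truth_boxes.items()},
                "detections": {k: [list(d) for d in v] for k, v in ds.detections.items()},
            },
            indent=2,
        )
    )


def read_detections(path: str | Path) -> SyntheticDetectionSet:
    data = json.loads(Path(path).read_text())
    return SyntheticDetectionSet(
        images=data["images"],
        truth_boxes={k: [tuple(b) for b in v] for k, v in data["truth_boxes"].items()},
        detections={k: [tuple(d) for d in v] for k, v in data["detections"].items()},
    )


def write_episodes(episodes: Sequence[EatingEpisode], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {
                    "start_s": ep.start_s,
                    "end_s": ep.end_s,
                    "events": [[ev.start_s, ev.end_s] for ev in ep.events],
                }
                for ep in episodes
            ],
            indent=2,
        )
    )


def read_episodes(path: str | Path) -> list[EatingEpisode]:
    data = json.loads(Path(path).read_text())
    return [
        EatingEpisode(
            start_s=ep["start_s"],
            end_s=ep["end_s"],
            events=tuple(EatingEvent(a, b) for a, b in ep.get("events", [])),
        )
        for ep in data
    ]


def write_scalogram_png(image: ScalogramImage, path: str | Path) -> None:
    path = Path(path)
    Image.fromarray(image.pixels[:, :, 0], mode="L").save(path)
    sidecar = {
        "segment_id": image.segment_id,
        "start_time_s": image.start_time_s,
        "label": image.label,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_scalogram_png(path: str | Path) -> ScalogramImage:
    path = Path(path)
    pixels = np.asarray(Image.open(path), dtype=np.uint8)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ScalogramImage(
        pixels=pixels[:, :, None],
        segment_id=meta.get("segment_id", ""),
        start_time_s=meta.get("start_time_s", 0.0),
        label=meta.get("label"),
    )
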