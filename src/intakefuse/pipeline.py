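"""End-to-end orchestration: simulate -> scalograms -> CNN -> fusion -> episodes.

``run_pipeline`` executes the full method on synthetic data: it generates
train/validation/test recordings, converts each 15-s segment to a scalogram
image, trains the sensor CNN, emulates the image-detector confidence streams,
selects the temporal lag n by grid search, trains the cost-sensitive random
forest on the fused predictor vectors, aggregates test predictions into
eating episodes and reports segment- and episode-level metrics for the fused
system next to image-only and sensor-only baselines. Everything is derived
from one global seed; two runs with the same config produce identical
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import episodes as ep
from .evaluation import ConfusionCounts, mcnemar_test, segment_metrics
from .fusion import (
    ConfidenceSeries,
    FusionParams,
    build_predictor_vectors,
    grid_search_n,
    predict_fused,
    train_fusion,
)
from .scalogram import CWTConfig, segment_signal, segment_to_image
from .sensor_model import ModelConfig, predict_proba, train_sensor_model
from .synthetic import (
    LabeledRecording,
    ScoreStreamConfig,
    SimulationConfig,
    simulate_recording,
    simulate_score_streams,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration of the full demo pipeline.

    Sub-configs mirror each stage's own config; per-stage seeds are derived
    deterministically from the global ``seed`` at run time, so one integer
    reproduces the entire run.
    """

    seed: int = 0
    # train_sim (CNN): a dense recording with many short episodes, so the
    # network sees a spread of chewing frequencies and orientations (a
    # stand-in for the many meals of a multi-subject training corpus).
    # fusion_sim / val_sim / test_sim: free-living episode statistics (few
    # distinct meals, long gaps) — the fusion forest is sensitive to the
    # intake prior, so it trains on the distribution it is evaluated on.
    train_sim: SimulationConfig = SimulationConfig(
        duration_s=3300.0, n_episodes=10,
        episode_duration_range_s=(60.0, 180.0),
        inter_episode_gap_range_s=(60.0, 240.0),
    )
    fusion_sim: SimulationConfig = SimulationConfig(
        duration_s=7200.0, n_episodes=4,
        inter_episode_gap_range_s=(960.0, 1500.0),
    )
    val_sim: SimulationConfig = SimulationConfig(
        duration_s=3600.0, n_episodes=2,
        inter_episode_gap_range_s=(960.0, 1500.0),
    )
    test_sim: SimulationConfig = SimulationConfig()
    scores: ScoreStreamConfig = ScoreStreamConfig()
    cwt: CWTConfig = CWTConfig()
    model: ModelConfig = ModelConfig()
    fusion: FusionParams = FusionParams()
    n_range: tuple[int, ...] = (0, 1, 2, 3, 4)
    merge_gap_min: float = 15.0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        """Build from a nested mapping (YAML/JSON), rejecting unknown keys."""
        sections = {
            "train_sim": SimulationConfig,
            "fusion_sim": SimulationConfig,
            "val_sim": SimulationConfig,
            "test_sim": SimulationConfig,
            "scores": ScoreStreamConfig,
            "cwt": CWTConfig,
            "model": ModelConfig,
            "fusion": FusionParams,
        }
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key in sections:
                klass = sections[key]
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(value) - known
                if unknown:
                    raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
                value = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                kwargs[key] = klass(**value)
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = tuple(value) if isinstance(value, list) else value
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _derive_seeds(seed: int, n: int) -> list[int]:
    # stable small integers; keep them below 2**31
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def scalograms_for(recording: LabeledRecording, cwt: CWTConfig) -> list:
    segs = segment_signal(recording.signal, recording.sample_rate_hz)
    return [
        segment_to_image(s, cwt, segment_id=f"seg_{i:04d}",
                         label=int(recording.segment_labels[i]))
        for i, s in enumerate(segs)
    ]


def _series_with_sensor(
    recording: LabeledRecording,
    scalograms: list,
    sensor_model,
    score_cfg: ScoreStreamConfig,
) -> ConfidenceSeries:
    """Image streams from the detector emulator, Ss from the trained CNN."""
    sim = simulate_score_streams(recording.segment_labels, score_cfg)
    ss = predict_proba(sensor_model, scalograms)[:, 1]
    return ConfidenceSeries(
        t_start_s=sim.t_start_s,
        sf=sim.sf,
        sb=sim.sb,
        ss=np.clip(ss, 0.0, 1.0),
        label=sim.label,
        missing=sim.missing,
    )


def _episode_eval(
    labels_pred: np.ndarray,
    t_start: np.ndarray,
    truth_episodes,
    gap_min: float,
) -> dict:
    events = ep.segments_to_events(labels_pred, t_start)
    merged = ep.merge_events_to_episodes(events, gap_min)
    truth = ep.merge_events_to_episodes(
        [ep.EatingEvent(s, e) for s, e in truth_episodes], gap_min
    )
    conf = ep.match_episodes(merged, truth)
    denom_sens = conf.tp + conf.fn
    denom_prec = conf.tp + conf.fp
    return {
        "n_events": len(events),
        "n_episodes": len(merged),
        "n_truth_episodes": len(truth),
        "tp": conf.tp,
        "fp": conf.fp,
        "fn": conf.fn,
        "sensitivity": conf.tp / denom_sens if denom_sens else float("nan"),
        "precision": conf.tp / denom_prec if denom_prec else float("nan"),
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages in dependency order and return the run report."""
    logging.basicConfig(level=config.log_level)
    seeds = _derive_seeds(config.seed, 7)
    train_sim = replace(config.train_sim, seed=seeds[0])
    fusion_sim = replace(config.fusion_sim, seed=seeds[1])
    val_sim = replace(config.val_sim, seed=seeds[2])
    test_sim = replace(config.test_sim, seed=seeds[3])
    model_cfg = replace(config.model, seed=seeds[4])
    fusion_params = replace(config.fusion, seed=seeds[5])

    logger.info("simulating recordings")
    rec = {"train": simulate_recording(train_sim),
           "fusion": simulate_recording(fusion_sim),
           "val": simulate_recording(val_sim),
           "test": simulate_recording(test_sim)}

    logger.info("computing scalograms")
    scal = {k: scalograms_for(r, config.cwt) for k, r in rec.items()}

    logger.info("training sensor CNN (%d scalograms)", len(scal["train"]))
    sensor = train_sensor_model(
        scal["train"], rec["train"].segment_labels, model_cfg
    )

    logger.info("building confidence series")
    series = {
        k: _series_with_sensor(
            rec[k], scal[k], sensor, replace(config.scores, seed=seeds[6] + i)
        )
        for i, k in enumerate(("fusion", "val", "test"))
    }

    logger.info("grid search over n")
    best_n, per_n = grid_search_n(
        series["fusion"], series["val"], config.n_range, fusion_params
    )

    fused = train_fusion(
        build_predictor_vectors(series["fusion"], best_n),
        series["fusion"].label,
        fusion_params,
        n=best_n,
    )
    y_test = series["test"].label
    pred_fused, _ = predict_fused(
        fused, build_predictor_vectors(series["test"], best_n)
    )

    # single-modality baselines: same classifier, restricted streams
    baselines = {}
    preds = {"fused": pred_fused}
    for name, streams in (("image_only", ("sf", "sb")), ("sensor_only", ("ss",))):
        m = train_fusion(
            build_predictor_vectors(series["fusion"], best_n, streams),
            series["fusion"].label,
            fusion_params,
            n=best_n,
            streams=streams,
        )
        p, _ = predict_fused(m, build_predictor_vectors(series["test"], best_n, streams))
        preds[name] = p
        baselines[name] = segment_metrics(ConfusionCounts.from_labels(y_test, p))

    report: dict[str, Any] = {
        "seed": config.seed,
        "counts": {
            k: {
                "n_samples": rec[k].n_samples,
                "n_segments": len(scal[k]),
                "n_intake_segments": int(rec[k].segment_labels.sum()),
                "n_truth_episodes": len(rec[k].truth_episodes),
            }
            for k in rec
        },
        "sensor_training_loss": sensor.training_log,
        "chosen_n": best_n,
        "grid_search_f1": {str(k): v for k, v in per_n.items()},
        "segment_metrics": {
            "fused": segment_metrics(ConfusionCounts.from_labels(y_test, pred_fused)),
            **baselines,
        },
        "episode_metrics": {
            name: _episode_eval(
                preds[name], series["test"].t_start_s,
                rec["test"].truth_episodes, config.merge_gap_min,
            )
            for name in preds
        },
    }

    # paired comparison of image-only vs fused segment errors
    err_img = preds["image_only"] != y_test
    err_fus = pred_fused != y_test
    e01 = int(np.sum(err_img & ~err_fus))
    e10 = int(np.sum(~err_img & err_fus))
    if e01 + e10 > 0:
        mc = mcnemar_test(e01, e10)
        report["mcnemar_image_vs_fused"] = {
            "e01": mc.e01, "e10": mc.e10, "chi_square": mc.chi_square,
            "critical_value": mc.critical_value, "reject": mc.reject,
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        (out_dir / "resolved_config.json").write_text(
            json.dumps(config.to_dict(), indent=2)
        )
    return report
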