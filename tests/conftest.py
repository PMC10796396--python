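"""Shared fixtures: a trained sensor CNN on the packaged synthetic benchmark.

Training the CNN takes a couple of CPU-minutes, so it happens once per
session: a 200-segment training recording with many short, varied chewing
episodes, plus a free-living-style held-out recording with three distinct
meals. Several tests (sensor recovery, fusion dominance, score separation)
reuse the result.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from intakefuse import (
    CWTConfig,
    ModelConfig,
    SimulationConfig,
    predict_proba,
    simulate_recording,
    train_sensor_model,
)
from intakefuse.pipeline import scalograms_for

TRAIN_SIM = SimulationConfig(
    duration_s=3000.0,
    n_episodes=10,
    episode_duration_range_s=(60.0, 180.0),
    inter_episode_gap_range_s=(60.0, 240.0),
    seed=11,
)
HELDOUT_SIM = SimulationConfig(
    duration_s=5400.0,
    n_episodes=3,
    episode_duration_range_s=(300.0, 600.0),
    inter_episode_gap_range_s=(960.0, 1800.0),
    seed=12,
)
# fusion-stage training data shares the free-living episode statistics of the
# held-out recording (the fusion forest is sensitive to the intake prior)
FUSION_SIM = SimulationConfig(
    duration_s=7200.0,
    n_episodes=4,
    episode_duration_range_s=(300.0, 600.0),
    inter_episode_gap_range_s=(960.0, 1500.0),
    seed=13,
)


@dataclasses.dataclass
class SensorBench:
    train_rec: object
    fusion_rec: object
    test_rec: object
    train_scalograms: list
    test_scalograms: list
    model: object
    ss_train: np.ndarray
    ss_fusion: np.ndarray
    ss_test: np.ndarray


@pytest.fixture(scope="session")
def sensor_bench() -> SensorBench:
    cwt = CWTConfig()
    train_rec = simulate_recording(TRAIN_SIM)
    fusion_rec = simulate_recording(FUSION_SIM)
    test_rec = simulate_recording(HELDOUT_SIM)
    train_scal = scalograms_for(train_rec, cwt)
    fusion_scal = scalograms_for(fusion_rec, cwt)
    test_scal = scalograms_for(test_rec, cwt)
    assert len(train_scal) == 200
    model = train_sensor_model(train_scal, train_rec.segment_labels, ModelConfig(seed=7))
    return SensorBench(
        train_rec=train_rec,
        fusion_rec=fusion_rec,
        test_rec=test_rec,
        train_scalograms=train_scal,
        test_scalograms=test_scal,
        model=model,
        ss_train=predict_proba(model, train_scal)[:, 1],
        ss_fusion=predict_proba(model, fusion_scal)[:, 1],
        ss_test=predict_proba(model, test_scal)[:, 1],
    )
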