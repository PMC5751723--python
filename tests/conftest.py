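"""Shared fixtures: one pipeline config, one trained classifier and a few
fully-run scenarios, all session-scoped because rendering and tracking a
scene takes seconds."""

from __future__ import annotations

import numpy as np
import pytest

from fallert.config import PipelineConfig
from fallert.experiment import build_training, run_scenario
from fallert.scene_synth import default_script


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def training_set(config):
    return build_training(base_seed=1, config=config)


@pytest.fixture(scope="session")
def walk_result(config, training_set):
    return run_scenario(default_script("WALK", seed=42), config, training_set)


@pytest.fixture(scope="session")
def fall_perp_result(config, training_set):
    return run_scenario(default_script("FALL_PERP", seed=43), config, training_set)


@pytest.fixture(scope="session")
def occluded_walk_result(config, training_set):
    return run_scenario(default_script("OCCLUDED_WALK", seed=44), config,
                        training_set)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def flat_background():
    """A textured static background frame used by foreground tests."""
    gen = np.random.default_rng(77)
    base = 90.0 + 18.0 * np.sin(np.arange(120)[:, None] * 0.21) \
        + 14.0 * np.cos(np.arange(160)[None, :] * 0.17)
    return np.clip(base + gen.normal(0, 2, size=(120, 160)), 0, 255).astype(np.uint8)
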