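"""Shared fixtures: synthetic scenes and pipeline runs.

Scenes are generated programmatically at test time; the heavier default
scene and its two pipeline runs are session-scoped so every test file can
reuse them without re-clustering.
"""

import warnings

import numpy as np
import pytest

from aznano import (
    PipelineConfig,
    SceneConfig,
    generate_scene,
    run_single_channel,
    run_two_channel,
)

warnings.filterwarnings("ignore", category=FutureWarning)

ACCEPTANCE_SEED = 1


@pytest.fixture(scope="session")
def default_scene():
    """20-AZ scene at the generator's default study conditions."""
    cfg = SceneConfig(seed=ACCEPTANCE_SEED)
    brp, rim, truth = generate_scene(cfg)
    return cfg, brp, rim, truth


@pytest.fixture(scope="session")
def clean_scene():
    """Zero-background, zero-extrasynaptic 20-AZ scene."""
    cfg = SceneConfig(seed=7, background_density=0.0, extrasynaptic_sc_rate=0)
    brp, rim, truth = generate_scene(cfg)
    return cfg, brp, rim, truth


@pytest.fixture(scope="session")
def small_clean_scene():
    """5-AZ clean scene for fast clustering tests."""
    cfg = SceneConfig(
        seed=3, n_az=5, field_size=(4000.0, 4000.0), background_density=0.0, extrasynaptic_sc_rate=0
    )
    brp, rim, truth = generate_scene(cfg)
    return cfg, brp, rim, truth


@pytest.fixture(scope="session")
def bundle_two(default_scene):
    cfg, brp, rim, truth = default_scene
    return run_two_channel(PipelineConfig(seed=cfg.seed), brp, rim)


@pytest.fixture(scope="session")
def bundle_single(default_scene):
    cfg, brp, rim, truth = default_scene
    return run_single_channel(PipelineConfig(seed=cfg.seed), brp, rim)


@pytest.fixture(scope="session")
def bundle_clean(clean_scene):
    cfg, brp, rim, truth = clean_scene
    return run_two_channel(PipelineConfig(seed=cfg.seed), brp, rim)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
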