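import numpy as np
import pytest

from vinemetrics.synthetic_vineyard import (
    GrassSpec,
    Terrain,
    VineJitter,
    build_scene,
    default_profiles,
    default_scene_config,
)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_scene():
    """One short row on flat terrain, deterministic."""
    cfg = default_scene_config(n_rows=1, n_vines=4)
    return build_scene(cfg, seed=11)


@pytest.fixture(scope="session")
def two_row_scene():
    cfg = default_scene_config(n_rows=2, n_vines=5)
    return build_scene(cfg, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def flat_scene(seed, n_vines=6, slope=0.0):
    cfg = default_scene_config(
        n_rows=1, n_vines=n_vines, terrain=Terrain(slope=slope)
    )
    return build_scene(cfg, seed)
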