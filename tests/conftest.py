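import dataclasses

import numpy as np
import pytest

from vwfstrings import RunConfig, SceneParams


@pytest.fixture
def small_params() -> SceneParams:
    """A fast, small FOV with the default optics and noise model."""
    return dataclasses.replace(
        SceneParams(),
        fov_shape_px=(256, 256),
        n_z_slices=5,
        n_agglomerates=2,
        seed=11,
    )


@pytest.fixture
def small_config(small_params) -> RunConfig:
    return RunConfig(scene=small_params, n_fov=4, n_experiments=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
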