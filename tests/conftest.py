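import numpy as np
import pytest

from notowave import ModelConfig


@pytest.fixture
def default_config() -> ModelConfig:
    return ModelConfig(seed=0)


@pytest.fixture
def small_config() -> ModelConfig:
    """A short lattice for fast exhaustive checks."""
    return ModelConfig(n_cells=20, t_max=60, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
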