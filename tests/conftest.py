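import numpy as np
import pytest

from geompot.network import ModelConfig, init_params
from geompot.synthetic import random_cluster


@pytest.fixture
def small_model():
    """A small but non-trivial model: 2 blocks, 32 channels, l_max = 2."""
    cfg = ModelConfig(
        n_blocks=2, hidden_dim=32, n_heads=4, n_rbf=8, l_max=2, cutoff=5.0
    )
    return cfg, init_params(cfg, seed=0)


@pytest.fixture
def tiny_model():
    cfg = ModelConfig(
        n_blocks=1, hidden_dim=16, n_heads=2, n_rbf=6, l_max=1, cutoff=5.0
    )
    return cfg, init_params(cfg, seed=1)


@pytest.fixture
def cluster6():
    return random_cluster(6, box_scale=4.0, min_separation=1.0, seed=42)


def random_rotation(seed):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
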