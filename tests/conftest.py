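import numpy as np
import pytest

from fieldnet import GrowthConfig, simulate_growth


@pytest.fixture(scope="session")
def small_net():
    """A 120-node uniform-fitness network with full histories."""
    cfg = GrowthConfig(
        n_nodes=120, m=2, beta=1.0, fitness_dist="uniform", seed=7,
        track_history=True, track_probabilities=True,
    )
    return simulate_growth(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
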