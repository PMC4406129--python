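import numpy as np
import pandas as pd
import pytest

from socsel import SimulationConfig, generate_arrivals, generate_detections


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete winter."""
    return SimulationConfig(
        n_individuals=150,
        n_feeders=9,
        n_weeks=10,
        flocks_per_feeder_day=8.0,
        mean_flock_size=5.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_winter(small_config):
    """One simulated winter shared by read-only tests."""
    pop = generate_arrivals(small_config)
    return generate_detections(pop, small_config)


def random_weighted_network(rng, n=30, density=0.3):
    """Random symmetric weight matrix in [0, 1] with zero diagonal."""
    W = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    on = rng.random(len(iu)) < density
    W[iu[on], ju[on]] = rng.random(on.sum())
    W = W + W.T
    return W
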