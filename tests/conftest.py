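import numpy as np
import pytest

from allomove import datasets
from allomove.simulate import SimulationConfig, default_truth, simulate_tracks


@pytest.fixture(scope="session")
def cohort():
    return datasets.narwhal_cohort()


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def small_sim(truth):
    """A small simulated dataset shared across tests (4 x 150 hourly steps)."""
    cfg = SimulationConfig(
        n_individuals=4,
        steps_per_individual=150,
        csi_values=[0.0, 0.19, 0.5, 0.72],
        truth=truth,
        missing_dive_prob=0.2,
        seed=5,
    )
    return simulate_tracks(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
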