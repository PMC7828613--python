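import numpy as np
import pytest

from hapstar.graphs import make_lattice_adjacency
from hapstar.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def lattice36():
    """6x6 rook lattice standing in for the 37-state map in fast tests."""
    return make_lattice_adjacency(6, 6)


@pytest.fixture(scope="session")
def small_cohort(lattice36):
    """~2,400 births from 800 mothers with the default mechanism."""
    cfg = SimulationConfig(n_mothers=800, seed=42)
    return simulate_cohort(cfg, lattice36)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
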