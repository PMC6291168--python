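"""Shared fixtures: cached synthetic datasets so the suite simulates once."""

import numpy as np
import pytest

from chromexpr import simulate as sim


@pytest.fixture(scope="session")
def noiseless_sim() -> sim.SimulationResult:
    """Default two-chromosome dataset with expression noise off: every
    planted structure is exactly recoverable."""
    return sim.simulate(sim.SimulationConfig(seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def default_sim() -> sim.SimulationResult:
    """Default dataset at the default noise level."""
    return sim.simulate(sim.SimulationConfig(seed=3))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
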