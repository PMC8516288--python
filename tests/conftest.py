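import numpy as np
import pytest

from mitowave import LagParams, SimulationConfig, simulate_expression_and_observe


@pytest.fixture(scope="session")
def lag_params():
    """The fitted desynchronization parameters used throughout."""
    return LagParams(tau_mit=67.0, mu=3.4, sigma=0.7)


@pytest.fixture(scope="session")
def small_truth():
    """A small synthetic experiment shared by pipeline-level tests."""
    config = SimulationConfig(seed=7, n_genes=150, n_tfs=12)
    return simulate_expression_and_observe(config)


@pytest.fixture(scope="session")
def noise_free_truth():
    """Noise-free synthetic experiment for exact-recovery checks."""
    config = SimulationConfig(seed=7, n_genes=200, n_tfs=15, noise_sd=0.0)
    return simulate_expression_and_observe(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
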