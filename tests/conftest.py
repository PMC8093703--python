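import numpy as np
import pytest

from intabund import MCMCConfig, ScenarioConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded dataset at the baseline scenario."""
    return generate_dataset(ScenarioConfig(seed=42))


@pytest.fixture(scope="session")
def desk_mcmc():
    """Shortened chains used throughout the suite: 3 x 5,000 / 2,500 / 5."""
    return MCMCConfig(n_chains=3, n_iter=5000, burn_in=2500, thin=5, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
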