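import numpy as np
import pytest

from mpes.config import MCMCConfig
from mpes.fixture import hta_fixture


@pytest.fixture(scope="session")
def fixture_studies():
    studies, _ = hta_fixture()
    return studies


@pytest.fixture(scope="session")
def fixture_markov_inputs():
    _, mk = hta_fixture()
    return mk


@pytest.fixture
def fast_mcmc():
    """Short sampler runs for structural tests (not accuracy-critical)."""
    return MCMCConfig(iterations=4_000, burnin=2_000, seed=42)


@pytest.fixture
def medium_mcmc():
    """Moderate runs where posterior summaries are asserted numerically."""
    return MCMCConfig(iterations=15_000, burnin=7_500, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
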