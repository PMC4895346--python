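import numpy as np
import pytest

from tfocc.pwm import PWM, PositionFrequencyMatrix, SiteList, \
    log_odds_from_probabilities
from tfocc.simulate import SimulationConfig, generate_bundle


def random_pfm(rng, length, name="toy"):
    """A random, reasonably informative PFM."""
    values = rng.dirichlet(np.full(4, 0.4), size=length)
    return PositionFrequencyMatrix(values, name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_pwm(rng) -> PWM:
    return log_odds_from_probabilities(random_pfm(rng, 5))


@pytest.fixture
def site_list() -> SiteList:
    return SiteList.from_records([
        ("chr1", 1000 + 500 * i, "+", 1.0, f"s{i}") for i in range(20)])


@pytest.fixture(scope="session")
def small_bundle():
    """A modest simulated study shared across tests (CTCF-like archetype)."""
    config = SimulationConfig(seed=11, n_sites=200, genome_length=500_000)
    return generate_bundle(config)
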