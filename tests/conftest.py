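import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popdens.core import PopulationConfig, ampa_synapse, default_neuron

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def neuron():
    return default_neuron()


@pytest.fixture(scope="session")
def ampa():
    return ampa_synapse()


@pytest.fixture(scope="session")
def cfg_ampa(neuron, ampa):
    """Study-condition configuration: N=10,000, c_s=200, single receptor."""
    return PopulationConfig(neuron, (ampa,), N=10_000)


@pytest.fixture(scope="session")
def cfg_small(neuron, ampa):
    """Reduced population for cheap Monte Carlo unit tests."""
    return PopulationConfig(neuron, (ampa,), N=500)
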