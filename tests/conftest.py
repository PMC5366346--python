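import numpy as np
import pytest

import legumorph as lm
from legumorph.synthetic import NoiseModel, SamplingSchedule, generate_observations

SPECIES = list(lm.packaged_species())


@pytest.fixture(scope="session")
def configs():
    return {name: lm.get_species(name) for name in SPECIES}


@pytest.fixture(scope="session")
def alfalfa(configs):
    return configs["alfalfa"]


@pytest.fixture(scope="session")
def white_clover(configs):
    return configs["white_clover"]


@pytest.fixture(scope="session")
def noiseless_alfalfa(alfalfa):
    """A noiseless synthetic dataset + truth for the alfalfa configuration."""
    return generate_observations(alfalfa, SamplingSchedule(horizon_days=40),
                                 NoiseModel.noiseless(), n_plants=1)


@pytest.fixture(scope="session")
def constant_20c():
    days = np.linspace(0.0, 10.0, 241)
    return lm.TemperatureSeries(days, np.full_like(days, 20.0))
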