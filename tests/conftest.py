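import numpy as np
import pytest

from coibayes import ClassifierParams, SimParams, Simulator


@pytest.fixture(scope="session")
def sim():
    """Default synthetic world: 5 orders x 2 families x 3 genera x 3 species
    x 2 sequences, 650 nt, 12% inter-genus / 2% intra-genus divergence."""
    return Simulator(SimParams(seed=20140319))


@pytest.fixture(scope="session")
def training_set(sim):
    return sim.training_set()


@pytest.fixture(scope="session")
def params():
    return ClassifierParams(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
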