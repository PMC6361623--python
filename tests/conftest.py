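import numpy as np
import pytest

from blgamma import cells, synapses


@pytest.fixture(scope="session")
def pn_a():
    return cells.load_archetype("PN_A")


@pytest.fixture(scope="session")
def pn_c():
    return cells.load_archetype("PN_C")


@pytest.fixture(scope="session")
def fsi():
    return cells.load_archetype("FSI")


@pytest.fixture(scope="session")
def synapse_classes():
    return synapses.load_synapse_classes()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
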