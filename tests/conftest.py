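import numpy as np
import pytest

from poresim.fixtures import make_chain
from poresim.network import build_full_lattice
from poresim.population import SpeciesParams


@pytest.fixture(scope="session")
def species_params():
    return (SpeciesParams.aerobe(), SpeciesParams.anaerobe())


@pytest.fixture(scope="session")
def ring1():
    return build_full_lattice(1)


@pytest.fixture(scope="session")
def lattice3():
    return build_full_lattice(3)


@pytest.fixture(scope="session")
def chain10():
    return make_chain(10)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
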