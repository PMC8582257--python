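import numpy as np
import pytest

from nanolego.corrections import bundled_registry
from nanolego.fixtures import load_fixture, synth_molecule


@pytest.fixture(scope="session")
def registry():
    return bundled_registry()


@pytest.fixture(scope="session")
def cysteine():
    return load_fixture("cysteine")


@pytest.fixture(scope="session")
def guanine():
    return load_fixture("guanine")


@pytest.fixture(scope="session")
def benzofuran():
    return load_fixture("benzofuran")


@pytest.fixture(scope="session")
def cmc():
    return load_fixture("cyanomethylenecyclopropane")


@pytest.fixture()
def rng():
    return np.random.default_rng(20210788)


@pytest.fixture()
def small_molecule():
    """A fixed 6-atom synthetic molecule used across refinement tests."""
    return synth_molecule(seed=11, n_atoms=6)
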