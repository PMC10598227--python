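import numpy as np
import pytest

from noetools.energy import EnergyModel, RefineConfig
from noetools.synthetic import FixtureConfig, make_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """The default 30-residue helix + docked S ligand."""
    return make_fixture(FixtureConfig())


@pytest.fixture(scope="session")
def small_fixture():
    """A 12-residue fragment used where refinement speed matters."""
    return make_fixture(FixtureConfig(sequence="ADKLVEAMTRLF"))


@pytest.fixture(scope="session")
def energy_model():
    return EnergyModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
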