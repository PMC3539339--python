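import numpy as np
import pytest

from qwasi.config import ModelSetup, default_chemical, default_environment
from qwasi.forcing import generate_forcings
from qwasi.solver import simulate
from qwasi.transfer import TransferConstants


@pytest.fixture(scope="session")
def chem():
    return default_chemical()


@pytest.fixture(scope="session")
def env():
    return default_environment()


@pytest.fixture(scope="session")
def constants():
    return TransferConstants()


@pytest.fixture(scope="session")
def setup():
    return ModelSetup()


@pytest.fixture(scope="session")
def full_forcing(setup):
    """The full May-through-February forcing window (7296 hours)."""
    return generate_forcings(7, chem=setup.chem, constants=setup.constants)


@pytest.fixture(scope="session")
def short_forcing(setup):
    """A two-month window for cheaper model-level tests."""
    return generate_forcings(
        11, start="2010-05-01", end="2010-06-30", chem=setup.chem, constants=setup.constants
    )


@pytest.fixture(scope="session")
def full_trajectory(setup, full_forcing):
    return simulate(setup.chem, setup.env, full_forcing, setup.constants)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
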