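import numpy as np
import pytest

from pmjp import fixtures
from pmjp.model import KineticLaw, PMJPModel, Reaction


@pytest.fixture(scope="session")
def lv():
    return fixtures.lotka_volterra()


@pytest.fixture(scope="session")
def sir():
    return fixtures.sir_finite()


@pytest.fixture(scope="session")
def sir_open():
    return fixtures.sir_open()


@pytest.fixture(scope="session")
def bd():
    return fixtures.birth_death()


@pytest.fixture(scope="session")
def toggle():
    return fixtures.toggle_switch()


@pytest.fixture(scope="session")
def small_bd():
    """Slow birth-death process convenient for exact grid-posterior oracles."""
    return fixtures.birth_death(theta=(3.0, 1.0))


@pytest.fixture(scope="session")
def telegraph():
    """Two-state on/off switch: constant activation, mass-action deactivation."""
    model = PMJPModel(
        ["G"],
        [
            Reaction("on", (1,), KineticLaw(indicators=[(0, 0)])),
            Reaction("off", (-1,), KineticLaw(mass_action=(1,))),
        ],
        (1.0, 1.5),
        [(1.0, 1.0), (1.0, 1.0)],
    )
    return model, np.array([0])
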