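import numpy as np
import pytest

from nanolink.simulate import (
    ForceField,
    LangevinParams,
    SimulationProtocol,
    init_configuration,
    run_langevin,
)
from nanolink.synthetic import make_diamond_network


@pytest.fixture(scope="session")
def diamond_single():
    """Valence-3 periodic diamond network, one sublattice."""
    return make_diamond_network((3, 3, 3), sublattices=1, seed=0)


@pytest.fixture(scope="session")
def diamond_double():
    """Valence-3 interpenetrated diamond network, two sublattices."""
    return make_diamond_network((3, 3, 3), sublattices=2, seed=0)


@pytest.fixture(scope="session")
def diamond_single_v4():
    """Full 4-valent diamond network (locally well-connected null)."""
    return make_diamond_network((3, 3, 3), sublattices=1, seed=0, max_valence=4)


@pytest.fixture(scope="session")
def diamond_double_v4():
    """Full 4-valent interpenetrated diamond network."""
    return make_diamond_network((3, 3, 3), sublattices=2, seed=0, max_valence=4)


@pytest.fixture(scope="session")
def small_gel():
    """One scaled-down gel trajectory (N = 60, rho = 0.10), shared by tests.

    Strong bonds (D0 = 20) gel quickly; a few hundred Brownian times is
    enough for a spanning bonded network at this density.
    """
    config = init_configuration(60, 0.10, seed=7)
    return run_langevin(
        config,
        ForceField(),
        LangevinParams(seed=17),
        SimulationProtocol(
            equilibration=10.0, production=250.0,
            frame_interval=50.0, stress_interval=0.5,
        ),
    )
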