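import numpy as np
import pytest

from aptapore.pnp import MeshOptions, PoreGeometry, SolverOptions, binary_electrolyte


@pytest.fixture
def pbs_binary():
    """Binary 1:1 reduction of 1x PBS (171.5 mol/m^3, Na+/Cl- diffusivities)."""
    return binary_electrolyte(171.5)


@pytest.fixture
def symmetric_electrolyte():
    """Equal-diffusivity 1:1 electrolyte (exact charge-conjugation symmetry)."""
    return binary_electrolyte(171.5, d_cation=1.5e-9, d_anion=1.5e-9)


@pytest.fixture
def pore_geom():
    """The study pore: 9.2 nm opening, taper angle pinned to 367 Mohm."""
    return PoreGeometry(tip_radius=4.6e-9, half_cone_angle=0.0926,
                        taper_length=5e-6)


@pytest.fixture
def fast_options():
    """Coarse mesh for solver tests that only check signs/ratios/invariants."""
    return SolverOptions(mesh=MeshOptions(n_r=48, n_theta=20))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
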