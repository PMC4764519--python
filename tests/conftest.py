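import numpy as np
import pytest

from fgpore.builder import generate_synthetic_fixture
from fgpore.forcefield import ForceFieldParams, default_force_field


@pytest.fixture(scope="session")
def ff():
    return default_force_field()


@pytest.fixture(scope="session")
def light_ff():
    """Lighter beads with proportionally softer bonds (same omega*dt);
    kinetics-only change used to keep sampling tests fast."""
    return ForceFieldParams(bead_mass=12.0, bond_stiffness=800.0)


@pytest.fixture(scope="session")
def fixture_bundle():
    """Scaled pore (L = 20 nm) with 16 synthetic FG chains."""
    return generate_synthetic_fixture(1.0 / 3.0, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def central_difference_forces(energy_fn, positions, h=1e-6):
    """Independent numerical-gradient oracle: F = -dE/dx."""
    num = np.zeros_like(positions)
    for i in range(positions.shape[0]):
        for c in range(3):
            p1 = positions.copy()
            p1[i, c] += h
            p2 = positions.copy()
            p2[i, c] -= h
            num[i, c] = -(energy_fn(p1) - energy_fn(p2)) / (2 * h)
    return num
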