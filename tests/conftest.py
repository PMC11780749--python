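import warnings

import numpy as np
import pytest

from gridbind.energy import EnergyTable, evaluate_grid
from gridbind.fixtures import water_like
from gridbind.se3_grid import build_se3_grid
from gridbind.sqra import SqRAParams, build_rate_matrix

# principal-frame warnings for near-symmetric fixtures are expected noise
warnings.filterwarnings(
    "ignore", message="near-degenerate principal moments of inertia"
)


@pytest.fixture(scope="session")
def water():
    return water_like()


@pytest.fixture(scope="session")
def tiny_grid():
    """3 radial x 12 direction x 8 orientation grid (288 cells)."""
    return build_se3_grid(0.2, 0.4, 3, 12, 8, seed=1)


@pytest.fixture(scope="session")
def tiny_water_rate(tiny_grid, water):
    energies = evaluate_grid(tiny_grid, water, water)
    params = SqRAParams(temperature=300.0, tau_c=0.1, mass=water.total_mass)
    return build_rate_matrix(tiny_grid, energies, params)


@pytest.fixture(scope="session")
def flat_tiny_rate(tiny_grid):
    """Flat-potential rate matrix on the tiny grid."""
    params = SqRAParams(temperature=300.0, diffusion=0.01)
    return build_rate_matrix(
        tiny_grid, EnergyTable(np.zeros(tiny_grid.n_cells)), params
    )
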