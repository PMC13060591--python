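import numpy as np
import pytest

from tntsim import (
    BoundaryConditions,
    ChipSpec,
    ConductivityGrid,
    GridSpec,
    build_geometry,
    conductivity_map,
    field_magnitude,
    smooth_field,
    solve_potential,
)


@pytest.fixture(scope="session")
def chip():
    return ChipSpec()


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def default_materials(chip, grid):
    return build_geometry(chip, grid, open_fraction=0.65, seed=1)


@pytest.fixture(scope="session")
def default_field(default_materials, grid):
    """Solved, conduction-corrected, mask-smoothed field for the default chip."""
    sigma = conductivity_map(default_materials)
    bc = BoundaryConditions.plate_electrodes(grid.n_rows, 200.0)
    phi = solve_potential(sigma, bc)
    fmap = field_magnitude(phi, sigma)
    conductive = sigma.sigma > 1e-6
    return smooth_field(fmap, 1.0, mask=conductive)


@pytest.fixture
def uniform_sigma():
    def make(n=100, value=0.5, spacing=1.2):
        return ConductivityGrid(sigma=np.full((n, n), float(value)), spacing=spacing)

    return make
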