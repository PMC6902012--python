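import numpy as np
import pytest

from normcomp import (
    GridSpec,
    SimulationParams,
    ellipsoid_mask,
    generate_constant_tsnr_image,
    generate_deformation,
)


@pytest.fixture(scope="session")
def desk_grid() -> GridSpec:
    return GridSpec.desk()


@pytest.fixture(scope="session")
def tiny_grid() -> GridSpec:
    """A grid small enough for brute-force oracles."""
    return GridSpec.from_shape((6, 6, 6))


@pytest.fixture(scope="session")
def default_image(desk_grid):
    """One default-parameter constant-tSNR image (mean 1000, tSNR 100, 190 t)."""
    return generate_constant_tsnr_image(SimulationParams(rng_seed=11), desk_grid)


@pytest.fixture(scope="session")
def smooth_field(desk_grid):
    """One seeded random warp at mid-range amplitude, with its inverse."""
    return generate_deformation(desk_grid, amplitude=3.0, smoothness=25.0, rng_seed=7)


@pytest.fixture(scope="session")
def desk_mask(desk_grid):
    return ellipsoid_mask(desk_grid)
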