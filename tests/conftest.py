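import numpy as np
import pytest

from crossmodal.synthetic import (
    LatentFieldSpec,
    ellipsoid_mask,
    generate_latent_fields,
    generate_spherical_parcellation,
)

GRID = (24, 24, 24)


@pytest.fixture(scope="session")
def grid():
    return GRID


@pytest.fixture(scope="session")
def mask(grid):
    return ellipsoid_mask(grid)


@pytest.fixture(scope="session")
def latents(grid):
    spec = LatentFieldSpec(grid_shape=grid, n_latents=3, smooth_fwhm_mm=24.0, seed=11)
    return generate_latent_fields(spec)


@pytest.fixture(scope="session")
def parc(grid, mask):
    return generate_spherical_parcellation(grid, mask, n_parcels=100, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
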