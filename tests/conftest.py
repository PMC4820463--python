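import numpy as np
import pytest
from hypothesis import settings

from plastec import ECConfig, ROISearchSpace, VoxelGrid
from plastec.synthetic import make_geometry

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def toy_config(seed: int = 0, **overrides) -> ECConfig:
    """Small search configuration for desk-scale synthetic ROIs."""
    params = dict(
        population_size=60,
        stall_generations=20,
        l_min=1,
        l_step=1,
        rng_seed=seed,
    )
    params.update(overrides)
    return ECConfig(**params)


@pytest.fixture(scope="session")
def small_geometry():
    """Deterministic pair of connected, disjoint ROIs on a 3 mm grid."""
    return make_geometry(shape=(8, 8, 8), roi_sizes=(40, 50), rng=12345)


@pytest.fixture(scope="session")
def small_spaces(small_geometry):
    grid, roi_a, roi_b = small_geometry
    return (
        ROISearchSpace(roi_a, grid, l_min=1, l_step=1),
        ROISearchSpace(roi_b, grid, l_min=1, l_step=1),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def unit_grid():
    """A 6x6x6 grid with 3 mm isotropic voxels."""
    return VoxelGrid(shape=(6, 6, 6), affine=np.diag([3.0, 3.0, 3.0, 1.0]))
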