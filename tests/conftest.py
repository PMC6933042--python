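import numpy as np
import pytest

from spectharm import (
    AcquisitionSettings,
    ActivityMap,
    voxelize,
)
from spectharm.data import load_phantom, load_profiles


@pytest.fixture(scope="session")
def small_spec():
    return load_phantom("small")


@pytest.fixture(scope="session")
def profiles_vs():
    return load_profiles("vendor-specific")


@pytest.fixture(scope="session")
def profiles_vn():
    return load_profiles("vendor-neutral")


@pytest.fixture(scope="session")
def profile_by_name(profiles_vs):
    return {p.name: p for p in profiles_vs}


@pytest.fixture(scope="session")
def truth_cache():
    """Shared rasterization cache; voxelized truths are seed-independent."""
    return {}


@pytest.fixture(scope="session")
def truth_small_48(small_spec, truth_cache):
    key = ("small", (4.8, 4.8, 4.8), 5)
    if key not in truth_cache:
        truth_cache[key] = voxelize(small_spec, 4.8)
    return truth_cache[key]


@pytest.fixture
def default_settings():
    return AcquisitionSettings(n_projections=128, time_per_projection_s=20.0)


def make_uniform_map(value=10.0, shape=(24, 24, 24), voxel=4.8):
    grid = np.full(shape, float(value))
    h = np.full(3, float(voxel))
    origin = -(np.asarray(shape) - 1) / 2.0 * h
    return ActivityMap(grid=grid, voxel_size_mm=h, origin_mm=origin)
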