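import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import voxatlas as va

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom: 64x32x32 voxels at 2 µm, symmetric."""
    return va.PhantomSpec(dims=(64, 32, 32), spacing_um=(2.0, 2.0, 2.0), seed=11)


@pytest.fixture(scope="session")
def phantom(small_spec):
    return va.make_phantom_brain(small_spec)


@pytest.fixture(scope="session")
def small_library(small_spec):
    """Registry + volumes + ground truth on the small phantom grid."""
    return va.make_registry(3, 3, 1, seed=11, spec=small_spec)


def random_volume(grid, seed, kind="normalized8", high=256):
    rng = np.random.default_rng(seed)
    data = rng.integers(0, high, size=grid.dims).astype(np.uint8)
    return va.Volume(grid, data, value_kind=kind)
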