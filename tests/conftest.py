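import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coroseg import BinaryMask, CTAVolume, PhantomConfig, make_phantom

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# A small, fast phantom used across module tests: 64^3 voxels at 0.625 mm,
# a 6 mm aorta and two short branches.
QUICK = dict(
    shape=(64, 64, 64),
    aorta_radius_mm=6.0,
    vessel_radii_mm=(2.5, 2.0),
    n_branches=2,
    branch_length_mm=14.0,
)


@pytest.fixture(scope="session")
def quick_phantom():
    return make_phantom(PhantomConfig(rng_seed=7, **QUICK))


@pytest.fixture(scope="session")
def quick_phantom_clean():
    return make_phantom(PhantomConfig(rng_seed=7, noise_sigma=0.0, **QUICK))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def straight_tube_mask(shape, p0, p1, radius, spacing=(1.0, 1.0, 1.0)):
    """Digitized straight tube (voxel-center membership), used as a fixture
    by several oracle tests."""
    sp = np.asarray(spacing, dtype=float)
    g = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ) * sp
    p0 = np.asarray(p0, dtype=float) * sp
    p1 = np.asarray(p1, dtype=float) * sp
    d = p1 - p0
    length = np.linalg.norm(d)
    d = d / length
    t = np.clip((g - p0) @ d, 0.0, length)
    closest = p0 + t[..., None] * d
    dist = np.linalg.norm(g - closest, axis=-1)
    return BinaryMask(dist <= radius, tuple(sp))


@pytest.fixture()
def tube_factory():
    return straight_tube_mask
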