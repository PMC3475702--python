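import numpy as np
import pytest

from budkit import DimensionlessParams
from budkit.fixtures import make_cap, make_flat, make_sphere_with_catenoid_neck


@pytest.fixture(scope="session")
def unit_dp() -> DimensionlessParams:
    """Neutral dimensionless parameters (kappa units, unit length scale)."""
    return DimensionlessParams(p_sigma=1.0, p_w=1.0, p_g=1.0, length_scale=1.0)


@pytest.fixture(scope="session")
def flat_fixture():
    return make_flat(radius=1.0)


@pytest.fixture(scope="session")
def hemisphere_fixture():
    return make_cap(0.5)


@pytest.fixture(scope="session")
def sphere_fixture():
    return make_cap(1.0)


@pytest.fixture(scope="session")
def neck_fixture():
    return make_sphere_with_catenoid_neck(bud_radius=1.0, neck_radius=0.15)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231114)


def random_profile(rng, n_modes_max=8, budding=False):
    """A random admissible tangent-angle profile (helper, not a fixture)."""
    from budkit.geometry import ShapeProfile

    n = int(rng.integers(2, n_modes_max + 1))
    scale = 2.0 if budding else 0.8
    amps = rng.uniform(-scale, scale, n) / np.arange(1, n + 1)
    s_ab = np.sort(rng.uniform(0.0, 1.0, 2))
    return ShapeProfile(amps, 1.0, float(s_ab[0]), float(s_ab[1]))
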