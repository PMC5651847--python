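import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from countershading import (
    SkyModel,
    leaf_reference_radiance,
    make_ellipsoid,
    optimal_reflectance,
    scene_pose,
    shading_curves,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the unclamped optimal map legitimately exceeds albedo 1 on shaded faces;
# silence the advisory warning during tests
logging.getLogger("countershading.countershade").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sky() -> SkyModel:
    """The experiments' light field: clear sky, sun at azimuth 270, altitude 45."""
    return SkyModel.clear_sky()


@pytest.fixture(scope="session")
def iso_sky() -> SkyModel:
    """Isotropic environment of radiance 2 everywhere (perfect diffuse ground)."""
    from countershading import ISOTROPIC

    return SkyModel(
        coefficients=ISOTROPIC, zenith_radiance=2.0, sun_irradiance=0.0, ground_albedo=1.0
    )


@pytest.fixture(scope="session")
def ref_mesh():
    """The caterpillar ellipsoid in the scene reference pose (broadside)."""
    return scene_pose(make_ellipsoid())


@pytest.fixture(scope="session")
def rad_leaf(sky) -> float:
    return leaf_reference_radiance(sky)


@pytest.fixture(scope="session")
def optimal_map(ref_mesh, sky, rad_leaf):
    return optimal_reflectance(ref_mesh, sky, rad_leaf)


@pytest.fixture(scope="session")
def curves(ref_mesh, sky, optimal_map):
    """The three jointly-normalized shading sweeps (pitch, roll, yaw)."""
    return shading_curves(ref_mesh, optimal_map, sky)


@pytest.fixture(scope="session")
def shading_lut(curves) -> dict:
    """Level -> normalized shading for the pitch sweep."""
    c = curves["pitch"]
    return dict(zip(c.levels, c.normalized))
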