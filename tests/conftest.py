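"""Shared fixtures: canister geometry, camera rings, and rendered scenes.

Expensive render/carve products are session-scoped so several tests can
share one computation.
"""

import pytest

import rootcarve as rc
from rootcarve.carve import CarveConfig, ViewEvidence, carve


@pytest.fixture(scope="session")
def cylinder() -> rc.Cylinder:
    return rc.Cylinder()


@pytest.fixture(scope="session")
def media() -> rc.OpticalMedia:
    return rc.OpticalMedia()


@pytest.fixture(scope="session")
def rig8() -> rc.TurntableRig:
    return rc.TurntableRig(n_views=8)


@pytest.fixture(scope="session")
def center_cube(cylinder) -> rc.AxisCube:
    """The 50-mm validation cube centered in the canister."""
    return rc.AxisCube(center=[0.0, 0.0, cylinder.height / 2.0], side=50.0)


@pytest.fixture(scope="session")
def cube_silhouettes_40(cylinder, center_cube):
    """40 equidistant-angle noise-free renders of the validation cube
    (straight rays, matched optics between render and carve)."""
    rig = rc.TurntableRig(n_views=40)
    views = rig.views(cylinder)
    sils = [
        rc.render_silhouette(
            center_cube, v, cylinder, refraction=False,
            grid_resolution=(800, 600), supersample=2,
        )
        for v in views
    ]
    return views, sils


@pytest.fixture(scope="session")
def cube_model_40(cylinder, cube_silhouettes_40):
    """Octree hull of the 50-mm cube carved at the study resolution."""
    views, sils = cube_silhouettes_40
    evidence = [ViewEvidence(v, s) for v, s in zip(views, sils)]
    return carve(evidence, CarveConfig(s_min=0.27), cylinder=cylinder)


@pytest.fixture(scope="session")
def small_cube_scene(cylinder, center_cube):
    """A cheap 8-view cube scene for structural tests."""
    rig = rc.TurntableRig(n_views=8)
    views = rig.views(cylinder)
    sils = [
        rc.render_silhouette(
            center_cube, v, cylinder, refraction=False,
            grid_resolution=(200, 150), supersample=2,
        )
        for v in views
    ]
    return views, sils
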