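import numpy as np
import pytest

from cysthead import phantom
from cysthead.volio import LandmarkSet, Volume


@pytest.fixture(scope="session")
def default_cysts():
    """Three detectable cysts plus one 0.8 mm decoy below the 1 mm rule."""
    return [
        phantom.CystSpec((0.0, 0.0, 2.0), 3.0),
        phantom.CystSpec((2.5, 0.0, -2.0), 2.0),
        phantom.CystSpec((-3.0, 1.0, 0.0), 1.5),
        phantom.CystSpec((0.0, -3.5, 0.5), 0.8),
    ]


@pytest.fixture(scope="session")
def head_phantom(default_cysts):
    """A small femoral-head phantom shared across detection tests."""
    spec = phantom.PhantomSpec(
        head_radius=8.0, voxel_size=0.2, cyst_specs=default_cysts, seed=7
    )
    volume, truth = phantom.generate_head(spec)
    return spec, volume, truth


def make_sphere_head(radius_mm=16.0, voxel=0.25, margin=1.0):
    """Analytic spherical head mask centred at the world origin."""
    n = int(np.ceil(2 * (radius_mm + margin) / voxel))
    origin = tuple(-(n - 1) / 2 * voxel for _ in range(3))
    grid = Volume(np.zeros((n, n, n), dtype=np.uint8), (voxel,) * 3, origin)
    cx, cy, cz = grid.index_grid_world()
    return grid.like(cx**2 + cy**2 + cz**2 <= radius_mm**2)


def sphere_landmarks(radius_mm=16.0):
    """Landmarks bisecting the sphere: fovea medial (+x), neck inferior."""
    return LandmarkSet(
        head_centre=(0.0, 0.0, 0.0),
        fovea_centre=(radius_mm, 0.0, 0.0),
        neck_centre=(0.0, 0.0, -radius_mm),
        mtd=(0.0, 0.0, 1.0),
        side="left",
    )


@pytest.fixture(scope="session")
def sphere_head_small():
    return make_sphere_head(radius_mm=8.0, voxel=0.25, margin=0.5)
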