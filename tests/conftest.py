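"""Shared fixtures: small synthetic orchards and clouds built at test time."""

import numpy as np
import pytest

from orchard_traits import (
    RasterGrid,
    ViewSpec,
    generate_orchard,
    generate_terrain,
    sample_point_cloud,
)


@pytest.fixture(scope="session")
def flat_terrain():
    """10 x 34 m flat terrain at 700 m, 5 cm cells."""
    return generate_terrain((0, 0, 34, 10), 0.05, mean_elevation=700.0, seed=0)


@pytest.fixture(scope="session")
def small_truth():
    """Six trees in two rows with the study's height range."""
    return generate_orchard(n_trees=6, n_rows=2, seed=3)


@pytest.fixture(scope="session")
def noiseless_view():
    return ViewSpec(
        inclination_deg=90.0, points_per_square_meter=250.0,
        noise_sd=0.0, tilt_angle_deg=0.0, seed=5,
    )


@pytest.fixture(scope="session")
def noiseless_cloud(small_truth, flat_terrain, noiseless_view):
    return sample_point_cloud(small_truth, flat_terrain, noiseless_view)


@pytest.fixture
def constant_grid():
    """Constant 703 m surface on a 40 x 40 grid of 0.1 m cells."""
    return RasterGrid(np.full((40, 40), 703.0), 0.1, origin=(0.0, 4.0))


def ellipsoid_surface_points(a, b, c, n, seed=0, half=False):
    """n points on (the upper half of) an ellipsoid surface."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    if half:
        u[:, 2] = np.abs(u[:, 2])
    return u * np.array([a, b, c])


def ellipsoid_solid_points(a, b, c, n, seed=0):
    """n points uniform inside an ellipsoid (rejection from the box)."""
    rng = np.random.default_rng(seed)
    pts = []
    while sum(len(p) for p in pts) < n:
        cand = rng.uniform(-1, 1, (2 * n, 3))
        keep = (cand**2).sum(axis=1) <= 1.0
        pts.append(cand[keep])
    return np.vstack(pts)[:n] * np.array([a, b, c])
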