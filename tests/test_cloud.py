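"""Point-cloud traits: tilt correction, filtering, segmentation, volumes."""

import numpy as np
import pytest

from orchard_traits import (
    PointCloud,
    ViewSpec,
    correct_tilt,
    crown_volumes,
    delineate_crown,
    filter_cloud,
    hull_volume,
    sample_point_cloud,
    segment_tree,
    tree_height,
    voxel_grid_volume,
)
from orchard_traits.cloud import (
    DegenerateGeometryError,
    EmptySelectionError,
    InsufficientPointsError,
)

from conftest import ellipsoid_solid_points, ellipsoid_surface_points

ELLIPSOID_AXES = (1.0, 0.8, 0.6)
ELLIPSOID_VOLUME = 4.0 / 3.0 * np.pi * np.prod(ELLIPSOID_AXES)


def level_ground_cloud(n=2000, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 10, (n, 2))
    z = np.full(n, 700.0) + rng.normal(0, noise, n)
    return PointCloud(np.column_stack([xy, z]))


def tilt_points(points, angle_deg, axis=(1.0, 0.0, 0.0)):
    a = np.radians(angle_deg)
    u = np.asarray(axis) / np.linalg.norm(axis)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
    centroid = points.mean(axis=0)
    return (points - centroid) @ R.T + centroid


class TestCorrectTilt:
    def test_level_cloud_unchanged(self):
        cloud = level_ground_cloud()
        out = correct_tilt(cloud)
        assert out.meta["tilt_correction_deg"] < 1e-6
        np.testing.assert_allclose(out.points, cloud.points, atol=1e-9)

    def test_injected_three_degree_tilt_recovered(self):
        cloud = level_ground_cloud(noise=0.005, seed=3)
        tilted = PointCloud(tilt_points(cloud.points, 3.0))
        out = correct_tilt(tilted)
        assert out.meta["tilt_correction_deg"] == pytest.approx(3.0, abs=0.1)
        # Ground residual after correction no worse than before.
        assert out.z.std() <= tilted.z.std()

    def test_pairwise_distances_preserved(self):
        cloud = level_ground_cloud(n=400, noise=0.3, seed=5)
        tilted = PointCloud(tilt_points(cloud.points, 5.0))
        out = correct_tilt(tilted)
        rng = np.random.default_rng(0)
        i, j = rng.integers(0, 400, (2, 200))
        before = np.linalg.norm(tilted.points[i] - tilted.points[j], axis=1)
        after = np.linalg.norm(out.points[i] - out.points[j], axis=1)
        np.testing.assert_allclose(after, before, rtol=1e-9)

    def test_orchard_cloud_tilt_recovery(self, small_truth, flat_terrain):
        view = ViewSpec(inclination_deg=65.0, noise_sd=0.01,
                        tilt_angle_deg=3.0, seed=21)
        cloud = sample_point_cloud(small_truth, flat_terrain, view)
        out = correct_tilt(cloud)
        assert out.meta["tilt_correction_deg"] == pytest.approx(3.0, abs=0.1)

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            correct_tilt(PointCloud(np.zeros((5, 3))))


class TestFilterCloud:
    def test_far_outlier_removed_cluster_intact(self):
        rng = np.random.default_rng(2)
        cluster = rng.normal(0, 0.5, (500, 3))
        cloud = PointCloud(np.vstack([cluster, [[100.0, 100.0, 100.0]]]))
        out = filter_cloud(cloud, k=8, sd_mult=2.0)
        assert len(out) == 500
        assert out.points[:, 0].max() < 50

    def test_voxel_downsampling_halves_paired_points(self):
        # Two points per 0.05 m voxel -> one centroid per voxel.
        base = np.stack(np.meshgrid(*[np.arange(5) * 0.05 + 0.01] * 3),
                        axis=-1).reshape(-1, 3)
        doubled = np.vstack([base, base + 0.005])
        out = filter_cloud(PointCloud(doubled), k=1, sd_mult=np.inf,
                           voxel_downsample=0.05)
        assert len(out) == len(base)

    def test_infinite_sd_mult_is_identity(self):
        cloud = level_ground_cloud(n=100)
        out = filter_cloud(cloud, k=4, sd_mult=np.inf)
        np.testing.assert_array_equal(out.points, cloud.points)

    def test_tiny_cloud_returned_with_warning(self):
        cloud = PointCloud(np.zeros((3, 3)))
        with pytest.warns(UserWarning):
            out = filter_cloud(cloud, k=8)
        assert len(out) == 3


class TestSegmentTree:
    def test_half_open_edges(self):
        cloud = PointCloud([[1.0, 1.0, 0.0], [2.0, 1.5, 0.0], [1.5, 1.5, 0.0]])
        out = segment_tree(cloud, (1.0, 1.0, 2.0, 2.0))
        # Min edge included, max edge excluded.
        assert len(out) == 2
        assert not (out.points[:, 0] == 2.0).any()

    def test_disjoint_extents_share_nothing(self, noiseless_cloud, small_truth):
        t0, t1 = small_truth.iloc[0], small_truth.iloc[1]
        a = segment_tree(noiseless_cloud, (t0.x - 1, t0.y - 1, t0.x + 1, t0.y + 1))
        b = segment_tree(noiseless_cloud, (t1.x - 1, t1.y - 1, t1.x + 1, t1.y + 1))
        assert len(a) + len(b) <= len(noiseless_cloud)

    def test_empty_extent_raises(self):
        cloud = PointCloud([[0.0, 0.0, 0.0]])
        with pytest.raises(EmptySelectionError):
            segment_tree(cloud, (5.0, 5.0, 6.0, 6.0), tree_id=3)


class TestTreeHeight:
    def test_direct_formula(self):
        assert tree_height(PointCloud([[0, 0, 700.0], [0, 1, 702.7]])) == \
            pytest.approx(2.7)

    def test_interior_point_leaves_height_unchanged(self):
        base = PointCloud([[0, 0, 700.0], [0, 1, 702.7]])
        more = PointCloud([[0, 0, 700.0], [0, 1, 702.7], [1, 1, 701.3]])
        assert tree_height(more) == tree_height(base)

    def test_synthetic_tree_matches_truth(self, noiseless_cloud, small_truth):
        for t in small_truth.itertuples():
            tree = segment_tree(
                noiseless_cloud,
                (t.x - t.rlong - 0.4, t.y - t.rtrans - 0.4,
                 t.x + t.rlong + 0.4, t.y + t.rtrans + 0.4),
            )
            assert tree_height(tree) == pytest.approx(t.total_h, abs=0.05)

    def test_single_point_raises(self):
        with pytest.raises(InsufficientPointsError):
            tree_height(PointCloud([[0, 0, 0]]))


class TestDelineateCrown:
    def test_zero_fraction_keeps_whole_tree(self):
        cloud = PointCloud(np.column_stack([np.zeros((50, 2)),
                                            np.linspace(700, 703, 50)]))
        assert len(delineate_crown(cloud, 0.0)) == 50

    def test_cut_level_arithmetic(self):
        z = np.linspace(700.0, 703.0, 61)
        cloud = PointCloud(np.column_stack([np.zeros((61, 2)), z]))
        crown = delineate_crown(cloud, 0.20)
        # H = 3, cut at 700.6.
        assert crown.z.min() >= 700.6 - 1e-12
        assert len(crown) == (z >= 700.6).sum()


class TestVoxelVolume:
    def test_single_point_single_voxel(self):
        assert voxel_grid_volume(PointCloud([[1, 2, 3]]), 0.1) == \
            pytest.approx(0.1**3)

    def test_dense_unit_cube(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 1, (120_000, 3))
        vol = voxel_grid_volume(PointCloud(pts), 0.1)
        assert vol == pytest.approx(1.0, abs=0.06)

    def test_dense_solid_ellipsoid(self):
        pts = ellipsoid_solid_points(*ELLIPSOID_AXES, n=150_000, seed=1)
        vol = voxel_grid_volume(PointCloud(pts), 0.05)
        assert vol == pytest.approx(ELLIPSOID_VOLUME, rel=0.10)

    def test_anchoring_shift_changes_at_most_one_shell(self):
        pts = ellipsoid_solid_points(*ELLIPSOID_AXES, n=40_000, seed=2)
        voxel = 0.1
        v0 = voxel_grid_volume(PointCloud(pts), voxel)
        v1 = voxel_grid_volume(PointCloud(pts + voxel / 3), voxel)
        n_shell = 2 * 8.0 / voxel**2  # generous surface-voxel estimate
        assert abs(v1 - v0) <= n_shell * voxel**3


class TestHullVolume:
    def test_unit_cube_corners(self):
        corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                            for k in (0, 1)], dtype=float)
        assert hull_volume(PointCloud(corners)) == pytest.approx(1.0, abs=1e-12)

    def test_regular_tetrahedron(self):
        # Edge-1 regular tetrahedron, V = 1 / (6 sqrt 2).
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / np.sqrt(8)
        assert hull_volume(PointCloud(pts)) == pytest.approx(1 / (6 * np.sqrt(2)),
                                                             rel=1e-12)

    def test_surface_ellipsoid_from_below(self):
        pts = ellipsoid_surface_points(*ELLIPSOID_AXES, n=2500, seed=3)
        vol = hull_volume(PointCloud(pts))
        assert vol <= ELLIPSOID_VOLUME
        assert vol == pytest.approx(ELLIPSOID_VOLUME, rel=0.03)

    def test_coplanar_points_raise(self):
        rng = np.random.default_rng(4)
        flat = np.column_stack([rng.uniform(0, 1, (50, 2)), np.zeros(50)])
        with pytest.raises(DegenerateGeometryError):
            hull_volume(PointCloud(flat))

    def test_matches_convex_hull_library(self):
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(5)
        pts = rng.normal(0, 1, (300, 3))
        assert hull_volume(PointCloud(pts)) == pytest.approx(
            ConvexHull(pts).volume, rel=1e-9
        )


class TestInvariants:
    def test_rigid_translation_invariance(self):
        pts = ellipsoid_surface_points(*ELLIPSOID_AXES, n=1500, seed=6)
        cloud = PointCloud(pts + [0, 0, 700])
        shifted = PointCloud(pts + [123.0, -45.0, 700])
        assert tree_height(shifted) == pytest.approx(tree_height(cloud),
                                                     rel=1e-9)
        assert hull_volume(shifted) == pytest.approx(hull_volume(cloud),
                                                     rel=1e-6)
        v0 = voxel_grid_volume(cloud, 0.1)
        v1 = voxel_grid_volume(shifted, 0.1)
        shell = 2 * 8.0 / 0.1**2 * 0.1**3
        assert abs(v1 - v0) <= shell

    def test_hull_below_truth_below_voxel(self):
        surf = ellipsoid_surface_points(*ELLIPSOID_AXES, n=3000, seed=8)
        solid = ellipsoid_solid_points(*ELLIPSOID_AXES, n=120_000, seed=8)
        hv = hull_volume(PointCloud(surf))
        voxel = 0.05
        vv = voxel_grid_volume(PointCloud(solid), voxel)
        shell = 8.0 / voxel**2 * voxel**3
        assert hv <= ELLIPSOID_VOLUME <= vv + shell

    def test_crown_volumes_bundle(self):
        pts = np.vstack([
            ellipsoid_surface_points(1.0, 1.0, 0.8, n=2000, seed=9,
                                     half=True) + [0, 0, 700.6],
            np.column_stack([np.zeros((30, 2)), np.linspace(700.0, 700.6, 30)]),
        ])
        res = crown_volumes(PointCloud(pts), tree_id=4, trunk_fraction=0.2,
                            voxel_size=0.1)
        assert res.tree_id == 4
        assert res.voxel_volume >= 0 and res.hull_volume >= 0
        ratio = res.voxel_volume / 0.1**3
        assert ratio == pytest.approx(round(ratio), abs=1e-9)
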