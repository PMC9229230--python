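"""Synthetic orchard with exact ground truth.

Generates the data products the trait pipeline consumes — a sloping
terrain raster, a table of trees with known dimensions, view-dependent
surface point clouds, and a maximum-z surface raster — so every
estimator can be scored against analytic truth.

The model orchard: rows of trees on a gently sloping plane, each tree a
vertical trunk carrying a half-ellipsoid crown (flat base at the trunk
top, vertical semi-axis equal to the crown depth). A sensor view is
summarized by an inclination angle (90 deg = nadir) and a set of
azimuths; a crown or ground patch is sampled only if its outward normal
faces the sensor for at least one azimuth, which reproduces the
mechanism by which nadir-only imagery misses the crown flanks that
oblique imagery sees. Gaussian coordinate noise and a small rigid tilt
of the whole cloud (the angular bias a real platform introduces) are
added last.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .cloud import PointCloud, merge_clouds
from .raster import NODATA, RasterGrid

TRUTH_COLUMNS = [
    "tree_id", "x", "y", "trunk_h", "total_h", "rlong", "rtrans", "true_vol", "row",
]


@dataclass
class ViewSpec:
    """One sensor viewing condition.

    inclination_deg: sensor elevation above the horizon, 90 = nadir.
    azimuths: compass directions (deg) the sensor is flown from.
    points_per_square_meter: surface sampling density.
    noise_sd: additive Gaussian coordinate noise (m).
    tilt_axis_deg / tilt_angle_deg: horizontal axis direction and
        magnitude of the rigid whole-cloud tilt (the angular bias).
    """

    inclination_deg: float = 90.0
    azimuths: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    points_per_square_meter: float = 300.0
    noise_sd: float = 0.02
    tilt_axis_deg: float = 0.0
    tilt_angle_deg: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.inclination_deg <= 90:
            raise ValueError("inclination must be in (0, 90]")
        if self.points_per_square_meter <= 0:
            raise ValueError("density must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.tilt_angle_deg <= 15:
            raise ValueError("tilt_angle_deg must be in [0, 15]")


def generate_terrain(
    extent: tuple[float, float, float, float],
    cell_size: float,
    mean_elevation: float = 700.0,
    slope: float = 0.0,
    roughness_sd: float = 0.0,
    seed: int = 0,
) -> RasterGrid:
    """Sloping-plane terrain raster with optional smooth roughness.

    Elevation = mean_elevation + slope * (x - x_center) plus a smoothed
    Gaussian field rescaled to standard deviation ``roughness_sd``.
    Deterministic given ``seed``.
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate extent")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    nx = int(np.ceil((xmax - xmin) / cell_size))
    ny = int(np.ceil((ymax - ymin) / cell_size))
    xs = xmin + (np.arange(nx) + 0.5) * cell_size
    x_center = (xmin + xmax) / 2.0
    values = np.broadcast_to(
        mean_elevation + slope * (xs - x_center), (ny, nx)
    ).copy()
    if roughness_sd > 0:
        rng = np.random.default_rng(seed)
        field_ = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), sigma=5.0)
        sd = field_.std()
        if sd > 0:
            values += field_ * (roughness_sd / sd)
    return RasterGrid(values, cell_size, origin=(xmin, ymax), nodata=NODATA)


def _half_ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Volume of a half ellipsoid with semi-axes a, b and height c."""
    return 2.0 / 3.0 * np.pi * a * b * c


def generate_orchard(
    n_trees: int = 20,
    n_rows: int = 2,
    spacing: float = 3.0,
    row_spacing: float = 4.0,
    height_range: tuple[float, float] = (2.13, 3.05),
    crown_ratio: float = 0.80,
    crown_radius_range: tuple[float, float] = (0.8, 1.3),
    jitter: float = 0.15,
    origin: tuple[float, float] = (2.0, 2.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth table for an orchard of row-planted trees.

    Trees fill ``n_rows`` rows along x with ``spacing`` between trees
    and ``row_spacing`` between rows (last row short if n_trees does not
    divide evenly), with positional jitter. Total heights are uniform on
    ``height_range``; trunk height is (1 - crown_ratio) of the total;
    crown semi-axes are uniform on ``crown_radius_range``; the analytic
    half-ellipsoid crown volume is recorded per tree.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    lo, hi = height_range
    if not 0 < lo < hi:
        raise ValueError("height_range must satisfy 0 < min < max")
    if not 0 < crown_ratio <= 1:
        raise ValueError("crown_ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    per_row = int(np.ceil(n_trees / n_rows))
    rows = []
    for tid in range(n_trees):
        row_id = tid // per_row
        pos_in_row = tid % per_row
        x = origin[0] + pos_in_row * spacing + rng.uniform(-jitter, jitter)
        y = origin[1] + row_id * row_spacing + rng.uniform(-jitter, jitter)
        total_h = rng.uniform(lo, hi)
        trunk_h = (1.0 - crown_ratio) * total_h
        rlong = rng.uniform(*crown_radius_range)
        rtrans = rng.uniform(*crown_radius_range)
        crown_depth = total_h - trunk_h
        rows.append(
            dict(
                tree_id=tid,
                x=x,
                y=y,
                trunk_h=trunk_h,
                total_h=total_h,
                rlong=rlong,
                rtrans=rtrans,
                true_vol=_half_ellipsoid_volume(rlong, rtrans, crown_depth),
                row=row_id,
            )
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def _view_directions(view: ViewSpec) -> np.ndarray:
    """Unit vectors pointing from the surface toward the sensor."""
    inc = np.radians(view.inclination_deg)
    az = np.radians(np.asarray(view.azimuths, dtype=float))
    return np.column_stack(
        [np.cos(az) * np.cos(inc), np.sin(az) * np.cos(inc),
         np.full(len(az), np.sin(inc))]
    )


def _terrain_z(terrain: RasterGrid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    row, col = terrain.index_of(x, y)
    ny, nx = terrain.shape
    row = np.clip(row, 0, ny - 1)
    col = np.clip(col, 0, nx - 1)
    return terrain.values[row, col]


def _tilt_rotation(axis_deg: float, angle_deg: float) -> np.ndarray:
    """Rotation by angle_deg about a horizontal axis at azimuth axis_deg."""
    t = np.radians(axis_deg)
    u = np.array([np.cos(t), np.sin(t), 0.0])
    a = np.radians(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def sample_point_cloud(
    truth: pd.DataFrame,
    terrain: RasterGrid,
    view: ViewSpec,
    ground_density: float | None = None,
) -> PointCloud:
    """View-dependent surface point cloud of the orchard.

    Crown points are drawn on each tree's half-ellipsoid surface and
    kept only where the outward normal faces the sensor (positive dot
    product with the view direction) for at least one azimuth. Ground
    points are drawn between trees (outside crown footprints) at
    ``ground_density`` (default: one fifth of the crown density —
    sparse ground returns). Gaussian noise of sd ``view.noise_sd`` is
    added to all coordinates, and the whole cloud is then rigidly
    rotated about its centroid by the view's tilt angle.

    Per-point labels ("canopy"/"ground") and pre-noise outward normals
    are recorded for downstream checks.
    """
    rng = np.random.default_rng(view.seed)
    dirs = _view_directions(view)
    if ground_density is None:
        ground_density = view.points_per_square_meter / 5.0

    pts_list: list[np.ndarray] = []
    normals_list: list[np.ndarray] = []
    labels_list: list[np.ndarray] = []

    for _, tree in truth.iterrows():
        a, b = float(tree.rlong), float(tree.rtrans)
        c = float(tree.total_h - tree.trunk_h)
        base_z = _terrain_z(terrain, np.array([tree.x]), np.array([tree.y]))[0]
        base_z += float(tree.trunk_h)
        # Thomsen's approximation of the half-ellipsoid surface area.
        p = 1.6075
        area = 2 * np.pi * ((a**p * b**p + a**p * c**p + b**p * c**p) / 3) ** (1 / p)
        n_raw = max(50, rng.poisson(area * view.points_per_square_meter))
        # Uniform on the upper unit hemisphere, then scaled to the ellipsoid.
        u = rng.standard_normal((n_raw, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        u[:, 2] = np.abs(u[:, 2])
        surf = u * np.array([a, b, c])
        # Outward normal of x^2/a^2 + y^2/b^2 + z^2/c^2 = 1 at the point.
        nrm = surf / np.array([a**2, b**2, c**2])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        visible = (nrm @ dirs.T > 0.0).any(axis=1)
        surf = surf[visible] + np.array([tree.x, tree.y, base_z])
        pts_list.append(surf)
        normals_list.append(nrm[visible])
        labels_list.append(np.full(len(surf), "canopy"))

    xmin, ymin, xmax, ymax = terrain.extent
    n_ground = rng.poisson(ground_density * (xmax - xmin) * (ymax - ymin))
    gx = rng.uniform(xmin, xmax, n_ground)
    gy = rng.uniform(ymin, ymax, n_ground)
    if len(truth):
        under_crown = np.zeros(n_ground, dtype=bool)
        for _, tree in truth.iterrows():
            under_crown |= (
                ((gx - tree.x) / tree.rlong) ** 2 + ((gy - tree.y) / tree.rtrans) ** 2
            ) <= 1.0
        gx, gy = gx[~under_crown], gy[~under_crown]
    else:
        warnings.warn("empty truth table: point cloud contains only ground")
    gz = _terrain_z(terrain, gx, gy)
    ground = np.column_stack([gx, gy, gz])
    pts_list.append(ground)
    normals_list.append(np.tile([0.0, 0.0, 1.0], (len(ground), 1)))
    labels_list.append(np.full(len(ground), "ground"))

    pts = np.vstack(pts_list)
    normals = np.vstack(normals_list)
    labels = np.concatenate(labels_list)

    if view.noise_sd > 0:
        pts = pts + rng.normal(0.0, view.noise_sd, pts.shape)
    if view.tilt_angle_deg != 0:
        R = _tilt_rotation(view.tilt_axis_deg, view.tilt_angle_deg)
        centroid = pts.mean(axis=0)
        pts = (pts - centroid) @ R.T + centroid
        normals = normals @ R.T
    cloud = PointCloud(pts, labels, normals, source=f"{view.inclination_deg:g}")
    cloud.meta["view"] = view
    return cloud


def rasterize_dsm(
    cloud: PointCloud,
    cell_size: float,
    extent: tuple[float, float, float, float],
) -> RasterGrid:
    """Surface raster: per-cell maximum z, empty cells nearest-filled."""
    if len(cloud) == 0:
        raise ValueError("cannot rasterize an empty cloud")
    xmin, ymin, xmax, ymax = extent
    nx = int(np.ceil((xmax - xmin) / cell_size))
    ny = int(np.ceil((ymax - ymin) / cell_size))
    grid = RasterGrid(np.full((ny, nx), NODATA), cell_size, (xmin, ymax))
    row, col = grid.index_of(cloud.points[:, 0], cloud.points[:, 1])
    ok = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
    if not ok.any():
        warnings.warn("extent covers no points; raster is all fill")
        return grid
    flat = row[ok] * nx + col[ok]
    values = np.full(ny * nx, -np.inf)
    np.maximum.at(values, flat, cloud.points[ok, 2])
    values = values.reshape(ny, nx)
    empty = ~np.isfinite(values)
    if empty.any() and (~empty).any():
        _, (ri, ci) = ndimage.distance_transform_edt(empty, return_indices=True)
        values = values[ri, ci]
    grid.values = values
    return grid


STANDARD_VIEWS = (90.0, 65.0, 45.0)


def make_view_set(
    inclinations: tuple[float, ...] = STANDARD_VIEWS,
    points_per_square_meter: float = 300.0,
    noise_sd: float = 0.02,
    tilt_angle_deg: float = 3.0,
    tilt_axis_deg: float = 0.0,
    seed: int = 0,
) -> dict[str, ViewSpec]:
    """One ViewSpec per standard sensor inclination, seeds decorrelated."""
    return {
        f"{inc:g}": ViewSpec(
            inclination_deg=inc,
            points_per_square_meter=points_per_square_meter,
            noise_sd=noise_sd,
            tilt_angle_deg=tilt_angle_deg,
            tilt_axis_deg=tilt_axis_deg,
            seed=seed + i,
        )
        for i, inc in enumerate(inclinations)
    }


def simulate_orchard_clouds(
    truth: pd.DataFrame,
    terrain: RasterGrid,
    views: dict[str, ViewSpec],
) -> dict[str, PointCloud]:
    """Per-view clouds plus their union as the "integrated" dataset."""
    clouds = {
        label: sample_point_cloud(truth, terrain, view)
        for label, view in views.items()
    }
    clouds["integrated"] = merge_clouds(list(clouds.values()), source="integrated")
    return clouds


def write_fixture_set(
    outdir: str | Path,
    truth: pd.DataFrame,
    dsm: RasterGrid,
    dtm: RasterGrid,
    clouds: dict[str, PointCloud],
) -> dict:
    """Write rasters, clouds and truth to ``outdir``; return a manifest."""
    from . import io as oio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"rasters": {}, "clouds": {}, "truth": "truth.csv"}
    truth.to_csv(outdir / "truth.csv", index=False)
    for name, grid in (("dsm", dsm), ("dtm", dtm)):
        path = outdir / f"{name}.asc"
        oio.write_ascii_grid(path, grid)
        manifest["rasters"][name] = path.name
    for label, cloud in clouds.items():
        path = outdir / f"cloud_{label}.xyz.csv"
        oio.write_xyz_csv(path, cloud)
        manifest["clouds"][label] = path.name
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
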