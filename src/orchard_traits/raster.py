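"""Raster canopy-height workflow.

Builds canopy height models (CHM = DSM - DTM) from gridded elevation
products, either with a delivered terrain model (T1) or with a terrain
model reconstructed by inverse-distance-weighted interpolation of ground
samples (T2); delineates per-tree canopy boundaries in three geometries
(polygon, bounding box, minimum enclosing circle); and computes per-tree
maximum height and pyramid crown volume.

Grid convention: row-major ``values[row, col]`` from the north-west
origin, square cells, half-open cell membership ``[x0, x0 + cell)``.
The cell (row, col) has its center at
``(x0 + (col + 0.5) * cell, y0 - (row + 0.5) * cell)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import shapely
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point, Polygon, box as shapely_box

NODATA = -9999.0

BoundaryKind = Literal["polygon", "box", "circle"]


class RasterAlignmentError(ValueError):
    """Two rasters cannot be brought onto a common grid."""


class EmptyZoneError(ValueError):
    """A boundary contains no raster cells."""


class MissingTreeError(ValueError):
    """A tree extent contains no canopy cells."""


class InsufficientSamplesError(ValueError):
    """Too few ground samples for interpolation."""


@dataclass
class RasterGrid:
    """Georeferenced single-band grid of elevations or heights (meters).

    Parameters
    ----------
    values : (ny, nx) float array
        Cell values; ``nodata`` marks missing cells.
    cell_size : float
        Square cell edge length in meters.
    origin : (float, float)
        Map coordinates of the north-west corner (x of the west edge,
        y of the north edge).
    nodata : float
        Sentinel for missing cells.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid."""
        ny, nx = self.values.shape
        x0, y0 = self.origin
        return (x0, y0 - ny * self.cell_size, x0 + nx * self.cell_size, y0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (x of columns, y of rows) of cell-center coordinates."""
        ny, nx = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = y0 - (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cells containing points (half-open cells)."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def mask_valid(self) -> np.ndarray:
        return self.values != self.nodata

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )


@dataclass
class TreeBoundary:
    """Canopy boundary of one tree in one of three geometries.

    ``geometry`` is a shapely polygon for all kinds; for circles the
    ``center`` and ``radius`` fields carry the exact parameters and the
    area is computed as pi r^2, not from the polygonal approximation.
    """

    tree_id: int
    kind: BoundaryKind
    geometry: Polygon
    area: float
    center: tuple[float, float] | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("boundary area must be positive")


@dataclass
class TraitRecord:
    """Per-tree trait estimate with method provenance."""

    tree_id: int
    method: str  # T1 | T2 | pointcloud | lidar
    dataset: str  # 45 | 65 | 90 | integrated | lidar
    height_m: float
    volume_m3: float
    boundary: str | None = None  # polygon | box | circle (raster methods)


def _resample_bilinear(src: RasterGrid, target: RasterGrid) -> RasterGrid:
    """Bilinear resampling of ``src`` onto ``target``'s grid."""
    xs, ys = src.cell_centers()
    # RegularGridInterpolator wants ascending axes; rows run north->south.
    vals = np.where(src.mask_valid(), src.values, np.nan)
    interp = RegularGridInterpolator(
        (ys[::-1], xs), vals[::-1, :], bounds_error=False, fill_value=np.nan
    )
    txs, tys = target.cell_centers()
    gx, gy = np.meshgrid(txs, tys)
    out = interp(np.column_stack([gy.ravel(), gx.ravel()])).reshape(gy.shape)
    out = np.where(np.isnan(out), src.nodata, out)
    return RasterGrid(out, target.cell_size, target.origin, nodata=src.nodata)


def compute_chm(dsm: RasterGrid, dtm: RasterGrid) -> RasterGrid:
    """Canopy height model: cellwise DSM - DTM, clamped at zero.

    The two rasters must cover overlapping ground; a terrain model on a
    different grid is resampled bilinearly onto the surface-model grid.
    Nodata in either input propagates to the output.
    """
    if not dsm.same_grid(dtm):
        ax = dsm.extent
        bx = dtm.extent
        if ax[2] <= bx[0] or bx[2] <= ax[0] or ax[3] <= bx[1] or bx[3] <= ax[1]:
            raise RasterAlignmentError("DSM and DTM extents are disjoint")
        dtm = _resample_bilinear(dtm, dsm)
    valid = dsm.mask_valid() & dtm.mask_valid()
    chm = np.where(valid, np.maximum(dsm.values - dtm.values, 0.0), dsm.nodata)
    return RasterGrid(chm, dsm.cell_size, dsm.origin, nodata=dsm.nodata)


def sample_dtm_idw(
    dsm: RasterGrid,
    ground_points: Sequence[tuple[float, float]],
    power: float = 2.0,
    k_neighbors: int = 12,
) -> RasterGrid:
    """Terrain model from ground samples by inverse-distance weighting.

    Each ground point's elevation is read from the surface-model cell
    containing it (the point-sampling step); every output cell is then
    the IDW combination of its ``k_neighbors`` nearest samples with
    weights d^(-power). A cell whose center coincides with a sample
    (distance < cell_size / 10) returns that sample's elevation exactly.

    Parameters mirror common GIS practice: power 2, 12 neighbors.
    """
    pts = np.asarray(ground_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise InsufficientSamplesError("need at least 3 ground points (x, y)")
    xmin, ymin, xmax, ymax = dsm.extent
    inside = (
        (pts[:, 0] >= xmin) & (pts[:, 0] < xmax)
        & (pts[:, 1] > ymin) & (pts[:, 1] <= ymax)
    )
    pts = pts[inside]
    if len(pts) < 3:
        raise InsufficientSamplesError("fewer than 3 ground points inside the raster")
    row, col = dsm.index_of(pts[:, 0], pts[:, 1])
    z = dsm.values[row, col]
    ok = z != dsm.nodata
    pts, z = pts[ok], z[ok]
    if len(pts) < 3:
        raise InsufficientSamplesError("fewer than 3 ground points on valid cells")

    k = min(int(k_neighbors), len(pts))
    tree = cKDTree(pts)
    xs, ys = dsm.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    query = np.column_stack([gx.ravel(), gy.ravel()])
    dist, idx = tree.query(query, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    snap = dist[:, 0] < dsm.cell_size / 10.0
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    w[~np.isfinite(w)] = 0.0
    wsum = w.sum(axis=1)
    wsum[wsum == 0] = 1.0
    out = (w * z[idx]).sum(axis=1) / wsum
    out[snap] = z[idx[snap, 0]]
    return RasterGrid(
        out.reshape(dsm.values.shape), dsm.cell_size, dsm.origin, nodata=dsm.nodata
    )


def reclassify_canopy(chm: RasterGrid, height_threshold: float = 0.5) -> np.ndarray:
    """Binary canopy mask: cell is canopy iff CHM >= threshold (meters)."""
    if height_threshold <= 0:
        raise ValueError("height_threshold must be positive")
    return (chm.values >= height_threshold) & chm.mask_valid()


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected True component of a boolean array."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def extract_boundaries(
    mask: np.ndarray,
    grid: RasterGrid,
    tree_extents: Iterable[tuple[int, float, float, float, float]],
    kind: BoundaryKind = "polygon",
) -> list[TreeBoundary]:
    """Delineate one canopy boundary per tree from a canopy mask.

    ``tree_extents`` rows are ``(tree_id, xmin, ymin, xmax, ymax)`` map
    rectangles, one per tree (manual segmentation). Within each extent
    the largest 8-connected canopy component is taken, and the boundary
    is built as:

    - ``polygon``: union outline of the component's cells (area equals
      the shoelace area of that outline);
    - ``box``: axis-aligned bounding rectangle of the component's cells;
    - ``circle``: minimum enclosing circle of the component's cell
      centers, area pi r^2.
    """
    boundaries: list[TreeBoundary] = []
    ny, nx = mask.shape
    x0, y0 = grid.origin
    cell = grid.cell_size
    for tree_id, xmin, ymin, xmax, ymax in tree_extents:
        c0 = max(0, int(np.floor((xmin - x0) / cell)))
        c1 = min(nx, int(np.ceil((xmax - x0) / cell)))
        r0 = max(0, int(np.floor((y0 - ymax) / cell)))
        r1 = min(ny, int(np.ceil((y0 - ymin) / cell)))
        sub = np.zeros_like(mask)
        sub[r0:r1, c0:c1] = mask[r0:r1, c0:c1]
        comp = _largest_component(sub)
        rows, cols = np.nonzero(comp)
        if rows.size == 0:
            raise MissingTreeError(f"no canopy cells inside extent of tree {tree_id}")
        cx = x0 + (cols + 0.5) * cell
        cy = y0 - (rows + 0.5) * cell
        if kind == "polygon":
            # Union on the integer cell grid (exact shared edges), then
            # affine-map to world coordinates; float corners would leave
            # undissolved slivers.
            cells = [
                shapely_box(c, -(r + 1), c + 1, -r) for r, c in zip(rows, cols)
            ]
            geom = shapely.unary_union(cells)
            geom = shapely.transform(
                geom, lambda a: a * cell + np.array([x0, y0])
            )
            if geom.geom_type == "MultiPolygon":  # 8-connected diagonals touch at corners
                geom = max(geom.geoms, key=lambda g: g.area)
            boundaries.append(TreeBoundary(int(tree_id), "polygon", geom, geom.area))
        elif kind == "box":
            geom = shapely_box(
                cx.min() - cell / 2, cy.min() - cell / 2,
                cx.max() + cell / 2, cy.max() + cell / 2,
            )
            boundaries.append(TreeBoundary(int(tree_id), "box", geom, geom.area))
        elif kind == "circle":
            mp = MultiPoint(np.column_stack([cx, cy]))
            circ = shapely.minimum_bounding_circle(mp)
            radius = shapely.minimum_bounding_radius(mp)
            center = (circ.centroid.x, circ.centroid.y)
            boundaries.append(
                TreeBoundary(
                    int(tree_id), "circle", circ, float(np.pi * radius**2),
                    center=center, radius=float(radius),
                )
            )
        else:
            raise ValueError(f"unknown boundary kind: {kind!r}")
    return boundaries


def zonal_max_height(chm: RasterGrid, boundary: TreeBoundary) -> float:
    """Maximum CHM value over cells whose centers fall inside the boundary."""
    bxmin, bymin, bxmax, bymax = boundary.geometry.bounds
    xs, ys = chm.cell_centers()
    ci = np.nonzero((xs >= bxmin) & (xs <= bxmax))[0]
    ri = np.nonzero((ys >= bymin) & (ys <= bymax))[0]
    if ci.size == 0 or ri.size == 0:
        raise EmptyZoneError(f"boundary of tree {boundary.tree_id} overlaps no cells")
    gx, gy = np.meshgrid(xs[ci], ys[ri])
    inside = shapely.contains_xy(boundary.geometry, gx.ravel(), gy.ravel())
    vals = chm.values[np.ix_(ri, ci)].ravel()[inside]
    vals = vals[vals != chm.nodata]
    if vals.size == 0:
        raise EmptyZoneError(f"no valid cells inside boundary of tree {boundary.tree_id}")
    return float(vals.max())


def pyramid_crown_volume(
    boundary: TreeBoundary, max_height: float, crown_ratio: float = 0.80
) -> float:
    """Pyramid/cone crown volume from a boundary area and tree height.

    The crown is modeled as a pyramid over the boundary footprint whose
    height is ``crown_ratio`` (default 0.80) of the maximum tree height,
    excluding the trunk: V = (1/3) A H_eff for polygon and box
    boundaries, V = pi r^2 H_eff / 3 for circles (the same formula with
    A = pi r^2).
    """
    if max_height <= 0:
        raise ValueError("max_height must be positive")
    if not 0 < crown_ratio <= 1:
        raise ValueError("crown_ratio must be in (0, 1]")
    h_eff = crown_ratio * max_height
    if boundary.kind == "circle":
        assert boundary.radius is not None
        return float(np.pi * boundary.radius**2 * h_eff / 3.0)
    return float(boundary.area * h_eff / 3.0)
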