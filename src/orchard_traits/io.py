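"""Plain-text readers and writers for the pipeline's data products.

Rasters travel as single-band Esri ASCII grids (.asc, ``NODATA_value
-9999``); point clouds as XYZ CSV (``x,y,z`` header plus an optional
``label`` column); tables (truth, extents, traits, reference) as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import PointCloud
from .raster import NODATA, RasterGrid, TraitRecord


def write_ascii_grid(path: str | Path, grid: RasterGrid) -> None:
    """Write a raster as an Esri ASCII grid (xllcorner/yllcorner form)."""
    ny, nx = grid.shape
    xll = grid.origin[0]
    yll = grid.origin[1] - ny * grid.cell_size
    header = (
        f"ncols {nx}\n"
        f"nrows {ny}\n"
        f"xllcorner {xll!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values.astype(np.float32), fmt="%.4f")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an Esri ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    ny, nx = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(ny, nx)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + ny * cell)
    return RasterGrid(values, cell, origin, nodata=header.get("nodata_value", NODATA))


def write_xyz_csv(path: str | Path, cloud: PointCloud) -> None:
    """Write a point cloud as ``x,y,z[,label]`` CSV."""
    df = pd.DataFrame(cloud.points, columns=["x", "y", "z"])
    if cloud.labels is not None:
        df["label"] = cloud.labels
    df.to_csv(path, index=False, float_format="%.6f")


def read_xyz_csv(path: str | Path, source: str | None = None) -> PointCloud:
    """Read an ``x,y,z[,label]`` CSV point cloud."""
    df = pd.read_csv(path)
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return PointCloud(df[["x", "y", "z"]].to_numpy(), labels, source=source)


def read_extents_csv(path: str | Path) -> list[tuple[int, float, float, float, float]]:
    """Read per-tree extents from ``tree_id,xmin,ymin,xmax,ymax`` CSV."""
    df = pd.read_csv(path)
    return [
        (int(r.tree_id), float(r.xmin), float(r.ymin), float(r.xmax), float(r.ymax))
        for r in df.itertuples()
    ]


def extents_from_truth(
    truth: pd.DataFrame, margin: float = 0.3
) -> list[tuple[int, float, float, float, float]]:
    """Per-tree rectangles from the truth table: crown bounds + margin."""
    return [
        (
            int(t.tree_id),
            float(t.x - t.rlong - margin),
            float(t.y - t.rtrans - margin),
            float(t.x + t.rlong + margin),
            float(t.y + t.rtrans + margin),
        )
        for t in truth.itertuples()
    ]


def write_traits_csv(path: str | Path, records: list[TraitRecord]) -> pd.DataFrame:
    """Write trait records as tidy CSV; returns the frame written."""
    df = pd.DataFrame(
        [
            dict(
                tree_id=r.tree_id,
                dataset=r.dataset,
                method=r.method,
                boundary=r.boundary or "",
                height_m=r.height_m,
                volume_m3=r.volume_m3,
            )
            for r in records
        ]
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return df


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    return df
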