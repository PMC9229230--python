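"""End-to-end orchard trait pipeline.

Chains the four stages — simulate (optional), raster canopy-height
models (T1: delivered terrain; T2: terrain interpolated from sampled
ground points), point-cloud traits, and the statistical report — over
the full comparison grid of methods x datasets x boundary shapes.

The systematic tilt (angular bias) is treated as an artifact of the
point-cloud export: the rasterized surface/terrain products are built
from bias-free geometry, while the point-cloud route receives tilted
clouds and must correct them. The same random draw underlies both, so
the two routes see the same orchard.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cloud as pc
from . import io as oio
from . import raster as rs
from . import stats as st
from . import synthetic as syn

logger = logging.getLogger("orchard_traits")

BOUNDARY_KINDS = ("polygon", "box", "circle")


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run.

    Defaults reproduce the bundled synthetic study: 20 trees in 2 rows,
    heights uniform on [2.13, 3.05] m, three sensor inclinations
    (90/65/45 deg) plus their integration, 0.02 m coordinate noise and
    a 3 deg angular bias, 0.05 m raster cells, 0.80 crown ratio,
    0.5 m canopy reclassification cut, 0.1 m crown voxels, and a
    17-tree ground LiDAR subset.
    """

    outdir: str = "orchard_run"
    seed: int = 0
    simulate: bool = True
    # --- synthetic orchard ---
    n_trees: int = 20
    n_rows: int = 2
    tree_spacing: float = 3.0
    row_spacing: float = 4.0
    height_range: tuple[float, float] = (2.13, 3.05)
    crown_radius_range: tuple[float, float] = (0.8, 1.3)
    terrain_slope: float = 0.01
    terrain_roughness_sd: float = 0.0
    mean_elevation: float = 700.0
    points_per_square_meter: float = 300.0
    noise_sd: float = 0.02
    tilt_angle_deg: float = 3.0
    tilt_axis_deg: float = 0.0
    inclinations: tuple[float, ...] = syn.STANDARD_VIEWS
    lidar_n_trees: int = 17
    lidar_inclination_deg: float = 30.0
    lidar_density: float = 600.0
    # --- real-data inputs (used when simulate is False) ---
    dsm_paths: dict = field(default_factory=dict)  # label -> .asc
    dtm_path: str | None = None
    cloud_paths: dict = field(default_factory=dict)  # label -> .xyz.csv
    extents_path: str | None = None
    reference_path: str | None = None
    # --- method toggles ---
    run_t1: bool = True
    run_t2: bool = True
    run_pointcloud: bool = True
    run_lidar: bool = True
    boundary_kinds: tuple[str, ...] = BOUNDARY_KINDS
    # --- thresholds ---
    cell_size: float = 0.05
    canopy_threshold: float = 0.5
    crown_ratio: float = 0.80
    trunk_fraction: float = 0.20
    voxel_size: float = 0.1
    lidar_downsample: float = 0.03
    idw_power: float = 2.0
    idw_k: int = 12
    n_ground_samples: int = 100
    filter_k: int = 8
    filter_sd_mult: float = 2.0
    excluded_tree_ids: tuple[int, ...] | None = None  # None = auto (largest, 2nd row)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("height_range", "crown_radius_range", "inclinations",
                    "boundary_kinds", "excluded_tree_ids"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def stratified_ground_points(
    extent: tuple[float, float, float, float],
    n: int,
    seed: int,
    truth: pd.DataFrame | None = None,
    margin: float = 0.2,
) -> np.ndarray:
    """Grid-stratified random ground-sample locations.

    Points are drawn one per cell of a near-square stratification grid;
    locations falling inside a crown footprint (+margin) are rejected so
    the samples read bare terrain, mimicking an operator clicking points
    on visible ground.
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = extent
    aspect = (xmax - xmin) / (ymax - ymin)
    ncol = max(1, int(np.round(np.sqrt(n * aspect))))
    nrow = max(1, int(np.ceil(n / ncol)))
    pts = []
    attempts = 0
    while len(pts) < n and attempts < 50 * n:
        i = attempts % (ncol * nrow)
        cx = xmin + (i % ncol + rng.uniform()) * (xmax - xmin) / ncol
        cy = ymin + (i // ncol % nrow + rng.uniform()) * (ymax - ymin) / nrow
        attempts += 1
        if truth is not None and len(truth):
            d = ((cx - truth.x) / (truth.rlong + margin)) ** 2 + (
                (cy - truth.y) / (truth.rtrans + margin)
            ) ** 2
            if (d <= 1.0).any():
                continue
        pts.append((cx, cy))
    return np.asarray(pts)


def _orchard_extent(cfg: PipelineConfig) -> tuple[float, float, float, float]:
    per_row = int(np.ceil(cfg.n_trees / cfg.n_rows))
    return (
        0.0,
        0.0,
        4.0 + (per_row - 1) * cfg.tree_spacing,
        4.0 + (cfg.n_rows - 1) * cfg.row_spacing,
    )


def simulate_stage(cfg: PipelineConfig) -> dict:
    """Generate terrain, truth, per-view clouds and raster products."""
    extent = _orchard_extent(cfg)
    terrain = syn.generate_terrain(
        extent, cfg.cell_size, cfg.mean_elevation, cfg.terrain_slope,
        cfg.terrain_roughness_sd, seed=cfg.seed,
    )
    truth = syn.generate_orchard(
        cfg.n_trees, cfg.n_rows, cfg.tree_spacing, cfg.row_spacing,
        cfg.height_range, cfg.crown_ratio, cfg.crown_radius_range, seed=cfg.seed,
    )
    views = syn.make_view_set(
        cfg.inclinations, cfg.points_per_square_meter, cfg.noise_sd,
        cfg.tilt_angle_deg, cfg.tilt_axis_deg, seed=cfg.seed,
    )
    clouds = syn.simulate_orchard_clouds(truth, terrain, views)
    # Bias-free twins of the same draws feed the raster products.
    flat_views = {
        label: dataclasses.replace(v, tilt_angle_deg=0.0)
        for label, v in views.items()
    }
    product_clouds = syn.simulate_orchard_clouds(truth, terrain, flat_views)
    dsms = {
        label: syn.rasterize_dsm(c, cfg.cell_size, extent)
        for label, c in product_clouds.items()
    }
    lidar_cloud = None
    lidar_truth = truth.iloc[: cfg.lidar_n_trees]
    if cfg.run_lidar and len(lidar_truth):
        lidar_view = syn.ViewSpec(
            inclination_deg=cfg.lidar_inclination_deg,
            azimuths=tuple(np.arange(0, 360, 45.0)),
            points_per_square_meter=cfg.lidar_density,
            noise_sd=cfg.noise_sd / 2,
            tilt_angle_deg=cfg.tilt_angle_deg,
            tilt_axis_deg=cfg.tilt_axis_deg,
            seed=cfg.seed + 100,
        )
        lidar_cloud = syn.sample_point_cloud(lidar_truth, terrain, lidar_view)
        lidar_cloud.source = "lidar"
    for label, c in clouds.items():
        logger.info("simulate: cloud %s has %d points", label, len(c))
    return dict(
        extent=extent, terrain=terrain, truth=truth, clouds=clouds,
        dsms=dsms, lidar_cloud=lidar_cloud, lidar_truth=lidar_truth,
    )


def raster_stage(
    cfg: PipelineConfig,
    dsms: dict[str, rs.RasterGrid],
    dtm: rs.RasterGrid,
    extents: list[tuple[int, float, float, float, float]],
    truth: pd.DataFrame | None = None,
) -> list[rs.TraitRecord]:
    """T1/T2 canopy-height models and per-boundary traits per dataset."""
    records: list[rs.TraitRecord] = []
    for label, dsm in dsms.items():
        chms: dict[str, rs.RasterGrid] = {}
        if cfg.run_t1:
            chms["T1"] = rs.compute_chm(dsm, dtm)
        if cfg.run_t2:
            ground_xy = stratified_ground_points(
                dsm.extent, cfg.n_ground_samples, cfg.seed + 7, truth
            )
            dtm2 = rs.sample_dtm_idw(dsm, ground_xy, cfg.idw_power, cfg.idw_k)
            chms["T2"] = rs.compute_chm(dsm, dtm2)
        for method, chm in chms.items():
            mask = rs.reclassify_canopy(chm, cfg.canopy_threshold)
            logger.info(
                "chm %s/%s: %d canopy cells", label, method, int(mask.sum())
            )
            for kind in cfg.boundary_kinds:
                boundaries = rs.extract_boundaries(mask, chm, extents, kind)
                for b in boundaries:
                    h = rs.zonal_max_height(chm, b)
                    v = rs.pyramid_crown_volume(b, h, cfg.crown_ratio)
                    records.append(
                        rs.TraitRecord(b.tree_id, method, label, h, v, kind)
                    )
    return records


def cloud_stage(
    cfg: PipelineConfig,
    clouds: dict[str, pc.PointCloud],
    extents: list[tuple[int, float, float, float, float]],
    method: str = "pointcloud",
    downsample: float | None = None,
) -> list[rs.TraitRecord]:
    """Tilt-correct, filter and extract per-tree point-cloud traits."""
    records: list[rs.TraitRecord] = []
    for label, cloud in clouds.items():
        corrected = pc.correct_tilt(cloud)
        logger.info(
            "cloud %s: tilt correction %.2f deg",
            label, corrected.meta.get("tilt_correction_deg", float("nan")),
        )
        filtered = pc.filter_cloud(
            corrected, cfg.filter_k, cfg.filter_sd_mult, downsample
        )
        logger.info(
            "cloud %s: %d -> %d points after filtering",
            label, len(cloud), len(filtered),
        )
        for ext in extents:
            tree_id = ext[0]
            try:
                tree = pc.segment_tree(filtered, ext[1:], tree_id)
            except pc.EmptySelectionError:
                logger.warning("cloud %s: tree %d empty, skipped", label, tree_id)
                continue
            h = pc.tree_height(tree)
            result = pc.crown_volumes(
                tree, tree_id, cfg.trunk_fraction, cfg.voxel_size
            )
            vol = result.voxel_volume if method == "lidar" else result.hull_volume
            records.append(rs.TraitRecord(tree_id, method, label, h, vol))
    return records


def _auto_excluded(truth: pd.DataFrame) -> tuple[int, ...]:
    """Default outlier rule: the largest tree of the second row."""
    second = truth[truth.row == truth.row.max()]
    if second.empty:
        return ()
    return (int(second.loc[second.total_h.idxmax(), "tree_id"]),)


def report_stage(
    cfg: PipelineConfig,
    traits: pd.DataFrame,
    reference: pd.DataFrame,
    outdir: Path,
    excluded: tuple[int, ...],
) -> pd.DataFrame:
    """Correlations and distribution summaries over the full grid."""
    correlations: list[st.CorrelationResult] = []
    summaries: list[st.DistributionSummary] = []
    scatter: dict = {}
    violin: dict = {"ground height": reference.height_m.to_numpy()}
    for (method, dataset, boundary), grp in traits.groupby(
        ["method", "dataset", "boundary"], sort=True
    ):
        tag = f"{method}-{dataset}" + (f"-{boundary}" if boundary else "")
        excl = () if method == "lidar" else excluded
        for trait_col, ref_col, what in (
            ("height_m", "height_m", "height"),
            ("volume_m3", "volume_m3", "volume"),
        ):
            paired = st.exclude_outliers(grp, reference, excl, trait_col, ref_col)
            if len(paired) < 3:
                continue
            res = st.pearson_with_stars(
                paired.reference, paired.estimate, pair=f"{tag} {what} vs ground"
            )
            correlations.append(res)
            if what == "height":
                scatter[f"{tag} height"] = (
                    paired.reference.to_numpy(), paired.estimate.to_numpy()
                )
        summaries.append(
            st.summarize_distribution(grp.height_m, f"{tag} height")
        )
        if method == "pointcloud" and not boundary:
            violin[f"{dataset} height"] = grp.height_m.to_numpy()
    summaries.append(
        st.summarize_distribution(reference.height_m, "ground height")
    )
    st.build_report(outdir, correlations, summaries, scatter, violin)
    return st.correlations_frame(correlations)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every enabled stage; return paths and result frames."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_log: list[dict] = []

    def _log(stage: str) -> None:
        stage_log.append({"stage": stage, "elapsed_s": round(time.time() - t0, 2)})

    if cfg.simulate:
        sim = simulate_stage(cfg)
        truth = sim["truth"]
        dtm = sim["terrain"]
        dsms = sim["dsms"]
        clouds = sim["clouds"]
        extents = oio.extents_from_truth(truth)
        reference = truth.rename(
            columns={"total_h": "height_m", "true_vol": "volume_m3"}
        )[["tree_id", "height_m", "volume_m3"]]
        syn.write_fixture_set(
            outdir / "fixture", truth, dsms["integrated"], dtm, clouds
        )
    else:
        dtm = oio.read_ascii_grid(cfg.dtm_path)
        dsms = {lab: oio.read_ascii_grid(p) for lab, p in cfg.dsm_paths.items()}
        clouds = {
            lab: oio.read_xyz_csv(p, source=lab)
            for lab, p in cfg.cloud_paths.items()
        }
        extents = oio.read_extents_csv(cfg.extents_path)
        reference = pd.read_csv(cfg.reference_path)
        truth = None
        sim = {}
    _log("simulate" if cfg.simulate else "load")

    records: list[rs.TraitRecord] = []
    if cfg.run_t1 or cfg.run_t2:
        records += raster_stage(cfg, dsms, dtm, extents, truth)
        _log("chm")
    if cfg.run_pointcloud:
        records += cloud_stage(cfg, clouds, extents, method="pointcloud")
        _log("pointcloud")
    if cfg.run_lidar and sim.get("lidar_cloud") is not None:
        lidar_extents = [
            e for e in extents
            if e[0] in set(sim["lidar_truth"].tree_id.astype(int))
        ]
        records += cloud_stage(
            cfg, {"lidar": sim["lidar_cloud"]}, lidar_extents,
            method="lidar", downsample=cfg.lidar_downsample,
        )
        _log("lidar")

    traits = oio.write_traits_csv(outdir / "traits.csv", records)
    excluded = (
        cfg.excluded_tree_ids
        if cfg.excluded_tree_ids is not None
        else (_auto_excluded(truth) if truth is not None else ())
    )
    corr = report_stage(cfg, traits, reference, outdir / "report", tuple(excluded))
    _log("report")

    manifest = {
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "excluded_tree_ids": list(excluded),
        "stages": stage_log,
        "n_trait_records": len(traits),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return dict(
        outdir=outdir, traits=traits, correlations=corr,
        reference=reference, manifest=manifest,
    )
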