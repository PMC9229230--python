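# orchard-traits

Per-tree **height** and **crown volume** estimation for row-planted
orchards (e.g. peach) from the two kinds of data products a UAV or
ground LiDAR survey produces:

- **rasters** — a digital surface model (DSM) and digital terrain model
  (DTM), from which a canopy height model CHM = DSM − DTM is built and
  summarized per tree with zonal statistics;
- **3D point clouds** — from which height is read directly as
  H = Z<sub>max</sub> − Z<sub>min</sub> and crown volume is measured on
  the delineated crown.

The package implements the full comparison grid such a study runs:

| route | terrain source | height | crown volume |
|---|---|---|---|
| T1 | delivered DTM raster | zonal max of CHM | pyramid: V = ⅓ · A · (0.8 H) |
| T2 | DTM interpolated (IDW) from sampled ground points | zonal max of CHM | pyramid / cone: V = π r² (0.8 H) / 3 |
| point cloud | fitted ground plane (tilt correction) | Z<sub>max</sub> − Z<sub>min</sub> | tetrahedral (convex-hull) volume |
| LiDAR preset | fitted ground plane | Z<sub>max</sub> − Z<sub>min</sub> | voxel-grid volume |

Per-tree boundaries come in three geometries (polygon outline of the
canopy component, axis-aligned bounding box, minimum enclosing circle),
with A the boundary area, r the circle radius, and 0.8 the crown ratio
— the fraction of total tree height occupied by the photosynthetic
crown. Estimates are scored against reference measurements with Pearson
correlation at the 5% / 1% / 0.1% significance levels, least-squares
slope, and violin/box summaries.

Because real orchard surveys are rarely redistributable, the package
includes a **synthetic orchard generator** with exact ground truth:
sloping terrain, rows of ellipsoid-crowned trees, view-angle-dependent
surface sampling (a nadir sensor sees crown tops; oblique sensors at
65° or 45° also see crown flanks), Gaussian coordinate noise, sparse
ground returns, and a small rigid tilt of the whole cloud emulating the
angular bias of exported point clouds. Every estimator can therefore be
validated against analytic truth.

## Worked example

```python
from orchard_traits import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="demo_run", seed=1)
res = run_pipeline(cfg)
corr = res["correlations"]
print(corr[corr.pair.str.contains("height")][["pair", "n", "r", "stars", "slope"]]
      .head(4).to_string(index=False))
```

prints (seed 1):

```
                          pair  n        r stars    slope
    T1-45-box height vs ground 19 0.999175   *** 1.014693
 T1-45-circle height vs ground 19 0.999175   *** 1.014693
T1-45-polygon height vs ground 19 0.999175   *** 1.014693
    T1-65-box height vs ground 19 0.999099   *** 1.015168
```

Each row correlates one method's per-tree height estimates against the
ground-truth heights of the 20-tree synthetic orchard, after excluding
the anomalously large tree of the second row (hence n = 19). `r` is the
Pearson coefficient with `***` marking p < 0.001, and a slope near one
means the estimates track the reference without systematic scale bias.
The same run writes `demo_run/traits.csv` (577 per-tree trait records
across all methods, datasets and boundary shapes), a report directory
with `correlations.csv`, `summaries.csv` and figures, and a re-readable
fixture (rasters, clouds, truth) under `demo_run/fixture/`.

The same stages are scriptable from the shell:

```bash
orchard-traits run --config cfg.yaml --seed 1 --out demo_run
orchard-traits simulate --out fixtures
orchard-traits chm --dsm dsm.asc --dtm dtm.asc --extents trees.csv --shape box
orchard-traits cloud --in cloud_integrated.xyz.csv --extents trees.csv --method hull
orchard-traits report --traits traits.csv --reference ground.csv --exclude 12
```

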