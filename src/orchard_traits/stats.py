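"""Statistical comparison of estimated and reference traits.

Pearson correlations with star notation at the 5% / 1% / 0.1%
significance levels, least-squares slope and intercept, correlation
matrices across datasets, quartile summaries for violin/box displays,
and the single-outlier exclusion used when one anomalously large tree
would dominate the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (zero variance or n < 3)."""


@dataclass
class CorrelationResult:
    """Pearson correlation of one estimate/reference pair."""

    pair: str
    n: int
    r: float
    p_value: float
    stars: str
    slope: float
    intercept: float
    r_squared: float


@dataclass
class DistributionSummary:
    """Five-number summary backing a violin/box display."""

    label: str
    median: float
    q1: float
    q3: float
    min: float
    max: float
    n: int


def stars_for_p(p: float) -> str:
    """Significance stars: *** < 0.001, ** < 0.01, * < 0.05, else none.

    Boundary values fall in the less-significant class (p = 0.05 gets
    no star).
    """
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_with_stars(
    x: Sequence[float], y: Sequence[float], pair: str = ""
) -> CorrelationResult:
    """Pearson r with two-sided p-value, stars, and least-squares fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    if len(x) < 3:
        raise UndefinedCorrelationError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return CorrelationResult(
        pair=pair,
        n=len(x),
        r=float(r),
        p_value=float(p),
        stars=stars_for_p(float(p)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r) ** 2,
    )


def exclude_outliers(
    traits: pd.DataFrame,
    reference: pd.DataFrame,
    excluded_ids: Sequence[int] = (),
    value_col: str = "height_m",
    ref_col: str = "height_m",
) -> pd.DataFrame:
    """Inner-join traits to reference on tree_id, minus excluded trees.

    Returns a frame with columns ``tree_id``, ``estimate``,
    ``reference``; its length is the n entering the correlation.
    Excluded ids absent from the join produce a warning, not an error.
    """
    joined = traits.merge(reference, on="tree_id", suffixes=("_est", "_ref"))
    est_col = value_col + "_est" if value_col + "_est" in joined.columns else value_col
    rcol = ref_col + "_ref" if ref_col + "_ref" in joined.columns else ref_col
    missing = set(excluded_ids) - set(joined.tree_id)
    if missing:
        warnings.warn(f"excluded ids not present in the join: {sorted(missing)}")
    keep = ~joined.tree_id.isin(list(excluded_ids))
    out = joined.loc[keep, ["tree_id", est_col, rcol]].copy()
    out.columns = ["tree_id", "estimate", "reference"]
    return out.reset_index(drop=True)


def correlation_matrix(
    datasets: Mapping[str, Sequence[float]],
    reference: Sequence[float],
    reference_label: str = "ground",
) -> pd.DataFrame:
    """Symmetric matrix of CorrelationResult over reference + datasets.

    All vectors must be aligned on the same trees (same length, same
    order). The [i, j] cell holds the CorrelationResult of labels i and
    j; the diagonal is the self-correlation (r = 1).
    """
    vectors = {reference_label: np.asarray(reference, dtype=float)}
    for label, v in datasets.items():
        vectors[label] = np.asarray(v, dtype=float)
    n = len(vectors[reference_label])
    for label, v in vectors.items():
        if len(v) != n:
            raise ValueError(f"vector {label!r} misaligned: {len(v)} != {n}")
    labels = list(vectors)
    mat = pd.DataFrame(index=labels, columns=labels, dtype=object)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if j < i:
                mat.loc[a, b] = mat.loc[b, a]
            else:
                mat.loc[a, b] = pearson_with_stars(
                    vectors[a], vectors[b], pair=f"{a} vs {b}"
                )
    return mat


def summarize_distribution(
    values: Sequence[float], label: str = ""
) -> DistributionSummary:
    """Median and quartiles (inclusive linear interpolation), min, max."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty vector")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    return DistributionSummary(
        label=label,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(v.min()),
        max=float(v.max()),
        n=int(v.size),
    )


def correlations_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                pair=r.pair, n=r.n, r=r.r, p=r.p_value, stars=r.stars,
                slope=r.slope, intercept=r.intercept, r2=r.r_squared,
            )
            for r in results
        ]
    )


def summaries_frame(summaries: Sequence[DistributionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                label=s.label, median=s.median, q1=s.q1, q3=s.q3,
                min=s.min, max=s.max, n=s.n,
            )
            for s in summaries
        ]
    )


def build_report(
    outdir: str | Path,
    correlations: Sequence[CorrelationResult],
    summaries: Sequence[DistributionSummary],
    scatter_data: Mapping[str, tuple[Sequence[float], Sequence[float]]] | None = None,
    violin_data: Mapping[str, Sequence[float]] | None = None,
) -> dict:
    """Write correlations.csv, summaries.csv and (best-effort) figures.

    Plot failures degrade to CSV-only output with a logged warning, so
    headless or minimal environments still get the numeric report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corr_df = correlations_frame(correlations)
    summ_df = summaries_frame(summaries)
    corr_df.to_csv(outdir / "correlations.csv", index=False, float_format="%.6f")
    summ_df.to_csv(outdir / "summaries.csv", index=False, float_format="%.6f")
    written = {
        "correlations": str(outdir / "correlations.csv"),
        "summaries": str(outdir / "summaries.csv"),
        "figures": [],
    }
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if scatter_data:
            for name, (x, y) in scatter_data.items():
                fig, ax = plt.subplots(figsize=(4, 4))
                x = np.asarray(x, float)
                y = np.asarray(y, float)
                ax.scatter(x, y, s=18, alpha=0.8)
                res = pearson_with_stars(x, y, pair=name)
                xs = np.linspace(x.min(), x.max(), 10)
                ax.plot(xs, res.slope * xs + res.intercept, "r-", lw=1)
                ax.set_title(f"{name}\nr={res.r:.3f}{res.stars}, slope={res.slope:.2f}")
                ax.set_xlabel("reference")
                ax.set_ylabel("estimate")
                fig.tight_layout()
                path = outdir / f"scatter_{name.replace(' ', '_')}.png"
                fig.savefig(path, dpi=100)
                plt.close(fig)
                written["figures"].append(str(path))
        if violin_data:
            fig, ax = plt.subplots(figsize=(1.2 * len(violin_data) + 2, 4))
            labels = list(violin_data)
            data = [np.asarray(violin_data[k], float) for k in labels]
            ax.violinplot(data, showmedians=False)
            ax.boxplot(data, widths=0.12, medianprops=dict(color="red"))
            ax.set_xticks(range(1, len(labels) + 1), labels, rotation=45, ha="right")
            fig.tight_layout()
            path = outdir / "violin.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written["figures"].append(str(path))
    except Exception as err:  # pragma: no cover - plotting is best-effort
        warnings.warn(f"figure generation failed, CSV report kept: {err}")
    return written
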