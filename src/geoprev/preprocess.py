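"""Survey and covariate preprocessing.

Turns individual-level survey rows into cluster-level records, builds the
standardized design matrix, prunes collinear predictors, extracts gridded
covariates at (possibly displaced) cluster coordinates, and provides the
simultaneous-autoregressive (SAR) smoothness diagnostic that justifies
nearest-pixel extraction under coordinate displacement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .raster import Raster

logger = logging.getLogger(__name__)

__all__ = [
    "Standardizer",
    "aggregate_to_clusters",
    "standardize",
    "prune_collinear",
    "extract_at_points",
    "distance_to_water",
    "annual_mean",
    "sar_smoothness",
    "categorize_tertiles",
]


def aggregate_to_clusters(
    individuals: pd.DataFrame,
    outcome: str = "positive",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Collapse individual rows to one record per (cluster_id, year).

    ``n`` counts rows, ``y`` counts positive outcomes; covariates are
    averaged (means for continuous, proportions for 0/1 columns — the same
    arithmetic).  Rows lacking coordinates are dropped and the count logged.
    """
    required = {"cluster_id", "year", "x_km", "y_km", outcome}
    missing = required - set(individuals.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if individuals.empty:
        warnings.warn("no individual rows supplied; returning empty table")
        return pd.DataFrame(
            columns=["cluster_id", "year", "x_km", "y_km", "n", "y"]
        )
    has_coords = individuals[["x_km", "y_km"]].notna().all(axis=1)
    n_dropped = int((~has_coords).sum())
    if n_dropped:
        dropped_clusters = individuals.loc[~has_coords, "cluster_id"].nunique()
        logger.info(
            "dropped %d rows (%d clusters) lacking coordinates",
            n_dropped,
            dropped_clusters,
        )
    rows = individuals[has_coords]
    covariates = covariates or []
    agg = {"x_km": "first", "y_km": "first"}
    if "urban" in rows.columns:
        agg["urban"] = "first"
    agg.update({c: "mean" for c in covariates})
    grouped = rows.groupby(["cluster_id", "year"], sort=True)
    out = grouped.agg(agg)
    out["n"] = grouped.size()
    out["y"] = grouped[outcome].sum().astype(int)
    out = out.reset_index()
    front = ["cluster_id", "year", "x_km", "y_km", "n", "y"]
    return out[front + [c for c in out.columns if c not in front]]


@dataclass(frozen=True)
class Standardizer:
    """Stored (mean, sd) so grid covariates reuse the training scaling."""

    mean: float
    sd: float

    def transform(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize(column, name: str = "column") -> tuple[np.ndarray, Standardizer]:
    """Center to mean 0 and scale to (sample) sd 1."""
    x = np.asarray(column, dtype=float)
    if np.unique(x[np.isfinite(x)]).size < 2:
        raise ValueError(f"cannot standardize constant column {name!r}")
    mean = float(np.nanmean(x))
    sd = float(np.nanstd(x, ddof=1))
    scaler = Standardizer(mean=mean, sd=sd)
    return scaler.transform(x), scaler


def prune_collinear(
    table: pd.DataFrame,
    priority: list[str],
    threshold: float = 0.8,
) -> tuple[list[str], pd.DataFrame]:
    """Drop the lower-priority member of each |r| > threshold pair.

    ``priority`` ranks columns best-first and must cover every column that
    ends up in a conflicted pair.  Returns the retained columns (original
    order) and a report of (var_a, var_b, r, kept, dropped).

    Pairs are visited in priority order of the kept member, so with three
    mutually correlated columns only the top-priority one survives.
    """
    cols = list(table.columns)
    corr = table.corr(method="pearson")
    rank = {c: i for i, c in enumerate(priority)}
    dropped: set[str] = set()
    report_rows = []
    ordered = sorted(cols, key=lambda c: rank.get(c, np.inf))
    for keeper in ordered:
        if keeper in dropped:
            continue
        for other in cols:
            if other == keeper or other in dropped:
                continue
            r = corr.loc[keeper, other]
            if np.isfinite(r) and abs(r) > threshold:
                if keeper not in rank or other not in rank:
                    missing = [c for c in (keeper, other) if c not in rank]
                    raise ValueError(
                        f"no priority given for correlated column(s) {missing}"
                    )
                dropped.add(other)
                report_rows.append(
                    {
                        "var_a": keeper,
                        "var_b": other,
                        "r": float(r),
                        "kept": keeper,
                        "dropped": other,
                    }
                )
    retained = [c for c in cols if c not in dropped]
    return retained, pd.DataFrame(
        report_rows, columns=["var_a", "var_b", "r", "kept", "dropped"]
    )


def extract_at_points(surface: Raster, points) -> np.ndarray:
    """Nearest-pixel-center extraction (no interpolation).

    Points outside the raster snap to the nearest edge pixel (logged);
    nodata cells yield NaN.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    xmin, ymin, xmax, ymax = surface.bounds
    outside = (
        (points[:, 0] < xmin)
        | (points[:, 0] > xmax)
        | (points[:, 1] < ymin)
        | (points[:, 1] > ymax)
    )
    if outside.any():
        logger.info("%d points outside raster extent; snapped to edge", outside.sum())
    values = np.empty(len(points))
    for i, (x, y) in enumerate(points):
        r, c = surface.index_of(x, y)
        v = surface.data[r, c]
        values[i] = np.nan if surface.is_nodata(v) else v
    return values


def distance_to_water(points, geometries) -> np.ndarray:
    """Planar distance (km) from each point to the nearest water feature.

    ``geometries`` may be shapely geometries or GeoJSON-like mappings.
    Points inside a polygon are at distance zero.
    """
    geoms = []
    for g in geometries:
        geoms.append(g if isinstance(g, BaseGeometry) else shapely_shape(g))
    if not geoms:
        raise ValueError("no water geometries supplied")
    from shapely.geometry import Point

    points = np.atleast_2d(np.asarray(points, dtype=float))
    return np.array(
        [min(geom.distance(Point(x, y)) for geom in geoms) for x, y in points]
    )


def annual_mean(values: pd.Series | pd.DataFrame, year: int):
    """Mean of within-year observations, missing slices excluded.

    ``values`` is indexed by timestamp (or has a 'date' column); returns NaN
    with a warning if the year has no valid observations.
    """
    if isinstance(values, pd.DataFrame):
        values = values.set_index("date").iloc[:, 0]
    idx = pd.DatetimeIndex(values.index)
    in_year = values[idx.year == year].dropna()
    if in_year.empty:
        warnings.warn(f"no observations in year {year}")
        return np.nan
    return float(in_year.mean())


def _rook_weights(nrows: int, ncols: int) -> sp.csr_matrix:
    """Row-standardized rook-contiguity weight matrix for a full grid."""
    n = nrows * ncols
    rows, cols = [], []
    for r in range(nrows):
        for c in range(ncols):
            i = r * ncols + c
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    rows.append(i)
                    cols.append(rr * ncols + cc)
    w = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(w.sum(axis=1)).ravel()
    return sp.diags(1.0 / deg) @ w


def sar_smoothness(surface: Raster | np.ndarray, order: int = 1) -> float:
    """Maximum-likelihood SAR lag coefficient of a surface on its neighbors.

    Fits y = rho W y + alpha + eps with W the row-standardized rook weight
    matrix, by profiling the concentrated log-likelihood over rho.  The
    coefficient lies in (1/min eig, 1) and is near 1 for smooth surfaces —
    the regime in which nearest-pixel extraction under coordinate
    displacement is approximately unbiased — near 0 for white noise, and
    negative for checkerboard-like surfaces.  Invariant to affine rescaling
    of the surface.
    """
    if order != 1:
        raise NotImplementedError("only first-order (rook) neighborhoods")
    data = surface.data if isinstance(surface, Raster) else np.asarray(surface, float)
    if data.shape[0] < 3 or data.shape[1] < 3:
        raise ValueError("raster must be at least 3x3")
    y = data.ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("surface contains missing values")
    if np.ptp(y) == 0:
        raise ValueError("constant surface: zero variance")
    y = (y - y.mean()) / y.std()
    n = y.size
    w = _rook_weights(*data.shape)
    # W is similar to a symmetric matrix -> real eigenvalues
    deg = np.asarray((w != 0).sum(axis=1)).ravel().astype(float)
    # reconstruct binary adjacency degree for symmetrization
    a_sym = sp.diags(np.sqrt(deg)) @ w @ sp.diags(1.0 / np.sqrt(deg))
    eigvals = np.linalg.eigvalsh(a_sym.toarray())
    wy = w @ y

    def negloglik(rho: float) -> float:
        e = y - rho * wy
        e = e - e.mean()  # profile out the intercept
        sse = float(e @ e)
        logdet = float(np.sum(np.log(np.abs(1.0 - rho * eigvals))))
        return 0.5 * n * np.log(sse / n) - logdet

    lo = 1.0 / eigvals.min() + 1e-6
    res = minimize_scalar(negloglik, bounds=(lo, 1.0 - 1e-6), method="bounded")
    return float(res.x)


def categorize_tertiles(x, name: str = "column") -> np.ndarray:
    """Three-level categorization at the empirical tertiles (codes 0/1/2)."""
    x = np.asarray(x, dtype=float)
    q1, q2 = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
    if q1 == q2:
        raise ValueError(f"tertile cut points tie for {name!r}")
    return np.digitize(x, [q1, q2])
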