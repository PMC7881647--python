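"""Risk-surface products: gridded prediction, counts, admin aggregation,
relative change and trend classification.

All credible intervals are computed at draw level (quantiles are not
additive), and the location-level effect lambda is excluded at new pixels by
default — its variance is reported separately through the fitted
``sigma2_nonsp``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely.geometry import Point
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from .inference import PosteriorResult, posterior_linpred
from .selection import _design_for_new

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionGrid",
    "PixelPrediction",
    "AdminAggregate",
    "predict_grid",
    "infected_counts",
    "aggregate_admin",
    "relative_change",
    "classify_trend",
]


@dataclass
class PredictionGrid:
    """Pixel centers plus raw covariate values and population.

    ``covariates`` maps covariate name to either an (n_pix,) array (static)
    or a dict year -> (n_pix,) array (time-varying).  Covariate values are
    raw; the training standardization is applied at prediction time.
    """

    points: np.ndarray  # (n_pix, 2) km
    covariates: dict
    population: np.ndarray  # (n_pix,)
    resolution_km: float = 5.0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.population = np.asarray(self.population, dtype=float)
        if np.any(self.population < 0):
            raise ValueError("population must be nonnegative")
        if len(self.population) != len(self.points):
            raise ValueError("population not aligned with pixel centers")

    def covariate_frame(self, year: float) -> pd.DataFrame:
        cols = {}
        for name, val in self.covariates.items():
            if isinstance(val, dict):
                cols[name] = np.asarray(val[year], dtype=float)
            else:
                cols[name] = np.asarray(val, dtype=float)
        return pd.DataFrame(cols, index=np.arange(len(self.points)))


@dataclass
class PixelPrediction:
    year: float
    points: np.ndarray  # (n_pix, 2) pixel centers, km
    draws: np.ndarray  # (S, n_pix) prevalence draws, NaN where masked
    mask: np.ndarray  # True where the pixel is valid
    median: np.ndarray
    sd: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def predict_grid(
    result: PosteriorResult, grid: PredictionGrid, year: float
) -> PixelPrediction:
    """Per-pixel posterior prevalence draws and summaries for one year.

    Pixels with any missing covariate are masked (counted in the log).
    """
    frame = grid.covariate_frame(year)
    needed = list(result.structure.spec.covariates)
    missing_cols = [c for c in needed if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"grid lacks covariates {missing_cols}")
    valid = (
        np.ones(len(grid.points), dtype=bool)
        if frame.empty
        else frame[needed].notna().all(axis=1).to_numpy()
    )
    n_masked = int((~valid).sum())
    if n_masked:
        logger.info("%d pixels masked for missing covariates", n_masked)

    n_s = result.draws["beta0"].size
    draws = np.full((n_s, len(grid.points)), np.nan)
    if valid.any():
        x_new = _design_for_new(result, frame[valid])
        eta = posterior_linpred(result, grid.points[valid], x_new, year)
        draws[:, valid] = expit(eta)
    median = np.nanmedian(draws, axis=0) if valid.any() else np.full(len(valid), np.nan)
    with np.errstate(all="ignore"):
        return PixelPrediction(
            year=year,
            points=grid.points,
            draws=draws,
            mask=valid,
            median=np.where(valid, median, np.nan),
            sd=np.where(valid, np.nanstd(draws, axis=0), np.nan),
            lower=np.where(valid, np.nanquantile(draws, 0.025, axis=0), np.nan),
            upper=np.where(valid, np.nanquantile(draws, 0.975, axis=0), np.nan),
        )


def infected_counts(
    prediction: PixelPrediction, population: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-pixel infected-count draws and summaries (count = p x population).

    Summing pixel-level count *medians* does not equal the median of the
    summed draws; any aggregate below uses the summed draws.
    """
    population = np.asarray(population, dtype=float)
    if np.any(population < 0):
        raise ValueError("population must be nonnegative")
    count_draws = prediction.draws * population[None, :]
    return {
        "draws": count_draws,
        "median": np.nanmedian(count_draws, axis=0),
        "lower": np.nanquantile(count_draws, 0.025, axis=0),
        "upper": np.nanquantile(count_draws, 0.975, axis=0),
    }


@dataclass
class AdminAggregate:
    unit_id: str
    level: str
    year: float
    prevalence: tuple[float, float, float]  # median, 2.5%, 97.5%
    count: tuple[float, float, float]
    population: float


def _as_geometries(features) -> list[tuple[str, BaseGeometry]]:
    """Accept GeoJSON FeatureCollection dicts or (id, geometry) iterables."""
    if isinstance(features, dict) and features.get("type") == "FeatureCollection":
        out = []
        for feat in features["features"]:
            uid = str(feat.get("id", feat.get("properties", {}).get("id")))
            out.append((uid, shapely_shape(feat["geometry"])))
        return out
    out = []
    for uid, geom in features:
        geom = geom if isinstance(geom, BaseGeometry) else shapely_shape(geom)
        out.append((str(uid), geom))
    return out


def assign_pixels(points: np.ndarray, features) -> np.ndarray:
    """Unit id per pixel center (containment; boundary ties to smaller id)."""
    units = sorted(_as_geometries(features), key=lambda kv: kv[0])
    assigned = np.array([None] * len(points), dtype=object)
    for uid, geom in units:
        hit = np.array(
            [
                assigned[i] is None
                and (geom.contains(Point(*p)) or geom.touches(Point(*p)))
                for i, p in enumerate(points)
            ]
        )
        assigned[hit] = uid
    return assigned


def aggregate_admin(
    prediction: PixelPrediction,
    population: np.ndarray,
    features,
    level: str = "ADM1",
) -> list[AdminAggregate]:
    """Population-weighted aggregation of pixel draws to admin units.

    Per draw: unit prevalence = sum(p * pop) / sum(pop); unit count =
    sum(p * pop).  Summaries are taken over the aggregated draws.  Units
    with zero population are flagged (prevalence undefined).
    """
    population = np.asarray(population, dtype=float)
    unit_of = assign_pixels(prediction.points, features)
    out = []
    for uid in sorted({u for u in unit_of if u is not None}):
        sel = (unit_of == uid) & prediction.mask
        pop = population[sel]
        total_pop = float(pop.sum())
        if total_pop == 0:
            logger.warning("unit %s has zero population; prevalence undefined", uid)
            out.append(
                AdminAggregate(
                    unit_id=uid,
                    level=level,
                    year=prediction.year,
                    prevalence=(np.nan, np.nan, np.nan),
                    count=(0.0, 0.0, 0.0),
                    population=0.0,
                )
            )
            continue
        count_draws = prediction.draws[:, sel] @ pop
        prev_draws = count_draws / total_pop
        out.append(
            AdminAggregate(
                unit_id=uid,
                level=level,
                year=prediction.year,
                prevalence=tuple(
                    float(q) for q in np.percentile(prev_draws, [50.0, 2.5, 97.5])
                ),
                count=tuple(
                    float(q) for q in np.percentile(count_draws, [50.0, 2.5, 97.5])
                ),
                population=total_pop,
            )
        )
    return out


def relative_change(median_a: np.ndarray, median_b: np.ndarray) -> np.ndarray:
    """Per-pixel (p_a - p_b) / p_a, the earlier year first.

    Under this convention increases from a to b come out *negative*; the
    sign-flipped percentage is simply -100 times the result.  Pixels with
    p_a = 0 are masked (NaN).
    """
    a = np.asarray(median_a, dtype=float)
    b = np.asarray(median_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps are not on the same grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) / a
    return np.where(a == 0, np.nan, out)


def classify_trend(
    current: tuple[float, float, float],
    previous: tuple[float, float, float],
) -> str:
    """'decreasing' | 'increasing' | 'stable' for (median, lower95, upper95).

    Decreasing iff the current median falls below the previous lower bound;
    increasing iff above the previous upper bound; otherwise stable.
    """
    med_t = current[0]
    _, lo_prev, hi_prev = previous
    if med_t < lo_prev:
        return "decreasing"
    if med_t > hi_prev:
        return "increasing"
    return "stable"
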