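"""DHS-like synthetic survey generator with known ground truth.

Produces cluster locations (true + privacy-displaced coordinates), smooth
gridded covariate and population surfaces, a Matern space-time latent field,
and binomial outcomes through the logit link — so that preprocessing,
inference, selection, validation and mapping can all be exercised against a
known truth without any external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import cholesky, solve_triangular
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .model import TemporalSpec, temporal_projection
from .raster import Raster
from .spde import Mesh, SPDEParams, spatial_variance, spde_precision

__all__ = [
    "SimulationConfig",
    "SyntheticSurvey",
    "gen_covariate_surfaces",
    "sample_clusters",
    "simulate_field",
    "simulate_outcomes",
    "simulate_survey",
]

URBAN_MAX_KM = 2.0
RURAL_MAX_KM = 10.0
RURAL_REDUCED_MAX_KM = 5.0


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic survey, including every model truth value."""

    bounds: tuple[float, float, float, float] = (0.0, 0.0, 200.0, 200.0)
    years: tuple[float, ...] = (2007.0, 2011.0, 2014.0)
    n_clusters_per_year: int = 300
    urban_fraction: float = 0.3
    mean_respondents: float = 30.0
    beta0: float = -1.8
    beta: tuple[float, ...] = (0.4, -0.3)
    kappa: float = 0.06
    tau: float = 12.0  # sigma2_sp = 1/(4 pi kappa^2 tau^2) ~ 0.154
    nu: float = 1.0
    temporal_mode: str = "ar1"
    rho: float = 0.4
    sigma2_nonsp: float = 0.1
    covariate_smoothness: float = 3.0  # gaussian-filter sigma, in cells
    grid_shape: tuple[int, int] = (40, 40)
    population_mean: float = 500.0
    repeat_locations: bool = False  # reuse year-1 locations in later years
    dhs_one_percent_rule: bool = False  # 1% of rural clusters get the 10 km cap
    urban_max_km: float = URBAN_MAX_KM
    rural_max_km: float = RURAL_MAX_KM
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.bounds
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("degenerate domain bounds")
        if self.n_clusters_per_year < 1:
            raise ValueError("need at least one cluster per year")
        if self.mean_respondents < 1:
            raise ValueError("need at least one respondent per cluster")
        if abs(self.rho) >= 1:
            raise ValueError("|rho| must be < 1")
        if self.sigma2_nonsp <= 0:
            raise ValueError("variances must be positive")

    @property
    def spde(self) -> SPDEParams:
        return SPDEParams(kappa=self.kappa, tau=self.tau, nu=self.nu)

    @property
    def temporal(self) -> TemporalSpec:
        """Equally spaced knots spanning the survey years (AR1-compatible)."""
        knots = tuple(np.linspace(self.years[0], self.years[-1], len(self.years)))
        rho = self.rho if self.temporal_mode == "ar1" else None
        return TemporalSpec(knots=knots, mode=self.temporal_mode, rho=rho)

    @property
    def covariate_names(self) -> list[str]:
        return [f"cov{i + 1}" for i in range(len(self.beta))]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("bounds", "years", "beta", "grid_shape"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _grid_raster(config: SimulationConfig, data: np.ndarray) -> Raster:
    xmin, ymin, xmax, ymax = config.bounds
    nrows, ncols = config.grid_shape
    cell = max((xmax - xmin) / ncols, (ymax - ymin) / nrows)
    return Raster(data=data, xll=xmin, yll=ymin, cellsize=cell)


def gen_covariate_surfaces(config: SimulationConfig) -> dict[str, Raster]:
    """Smooth random covariate surfaces plus a positive population surface.

    Each covariate surface is Gaussian-filtered white noise rescaled to mean
    zero / unit variance; infinite smoothness degenerates to a constant
    (zero) surface.  The population surface is the exponential of a smooth
    field scaled to the configured mean.
    """
    nrows, ncols = config.grid_shape
    if nrows < 1 or ncols < 1:
        raise ValueError("grid resolution must be positive")
    rng = np.random.default_rng(config.seed)
    surfaces: dict[str, Raster] = {}
    for name in config.covariate_names + ["population"]:
        noise = rng.standard_normal((nrows, ncols))
        if np.isinf(config.covariate_smoothness):
            smooth = np.zeros_like(noise)
        else:
            smooth = gaussian_filter(
                noise, sigma=config.covariate_smoothness, mode="reflect"
            )
            sd = smooth.std()
            if sd > 0:
                smooth = (smooth - smooth.mean()) / sd
        if name == "population":
            data = config.population_mean * np.exp(0.5 * smooth)
            data *= config.population_mean / data.mean()
        else:
            data = smooth
        surfaces[name] = _grid_raster(config, data)
    return surfaces


def _displace(
    true_xy: np.ndarray, urban: np.ndarray, config: SimulationConfig, rng
) -> np.ndarray:
    n = len(true_xy)
    max_r = np.where(urban, config.urban_max_km, config.rural_max_km)
    if config.dhs_one_percent_rule:
        rural = ~urban
        reduced = rural & (rng.uniform(size=n) > 0.01)
        max_r = np.where(reduced, np.minimum(RURAL_REDUCED_MAX_KM, max_r), max_r)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    radius = rng.uniform(0.0, max_r)
    out = true_xy + radius[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
    xmin, ymin, xmax, ymax = config.bounds
    clipped = (
        (out[:, 0] < xmin) | (out[:, 0] > xmax) | (out[:, 1] < ymin) | (out[:, 1] > ymax)
    )
    if clipped.any():
        warnings.warn(f"{int(clipped.sum())} displaced points clipped to the domain")
    out[:, 0] = np.clip(out[:, 0], xmin, xmax)
    out[:, 1] = np.clip(out[:, 1], ymin, ymax)
    return out


def sample_clusters(config: SimulationConfig) -> pd.DataFrame:
    """Cluster locations with both true and displaced coordinates.

    Displacement: random direction, random distance uniform on [0, 2] km for
    urban and [0, 10] km for rural clusters (optionally the DHS 1% rule).
    Respondent counts are Poisson around the configured mean, truncated at 5.
    """
    rng = np.random.default_rng(config.seed + 1)
    xmin, ymin, xmax, ymax = config.bounds
    records = []
    n_per_year = config.n_clusters_per_year
    base_xy = None
    base_urban = None
    for year_idx, year in enumerate(config.years):
        if config.repeat_locations and base_xy is not None:
            true_xy, urban = base_xy, base_urban
        else:
            true_xy = np.column_stack(
                [
                    rng.uniform(xmin, xmax, size=n_per_year),
                    rng.uniform(ymin, ymax, size=n_per_year),
                ]
            )
            urban = rng.uniform(size=n_per_year) < config.urban_fraction
            if base_xy is None:
                base_xy, base_urban = true_xy, urban
        disp_xy = _displace(true_xy, urban, config, rng)
        n_resp = np.maximum(rng.poisson(config.mean_respondents, size=n_per_year), 5)
        for j in range(n_per_year):
            cluster_id = (
                f"c{j:04d}" if config.repeat_locations else f"c{year_idx}_{j:04d}"
            )
            records.append(
                {
                    "cluster_id": cluster_id,
                    "year": year,
                    "x_true": true_xy[j, 0],
                    "y_true": true_xy[j, 1],
                    "x_km": disp_xy[j, 0],
                    "y_km": disp_xy[j, 1],
                    "urban": bool(urban[j]),
                    "n": int(n_resp[j]),
                }
            )
    return pd.DataFrame.from_records(records)


def simulate_field(
    mesh: Mesh,
    spde: SPDEParams,
    temporal: TemporalSpec,
    seed: int = 0,
) -> np.ndarray:
    """Draw the latent field xi at mesh vertices x time knots, shape (G, T).

    AR1 mode: xi_t = rho xi_{t-1} + w_t with w_t ~ N(0, Qs^{-1}) and the
    stationary start Var(xi_1) = Qs^{-1} / (1 - rho^2).  Exchangeable mode:
    independent N(0, Qs^{-1}) fields per knot.
    """
    rng = np.random.default_rng(seed)
    q_s = spde_precision(mesh, spde).toarray()
    upper = cholesky(q_s, lower=False)
    g, t = mesh.n_vertices, temporal.n_knots

    def draw_w() -> np.ndarray:
        return solve_triangular(upper, rng.standard_normal(g), lower=False)

    xi = np.empty((g, t))
    if temporal.mode == "exchangeable":
        for k in range(t):
            xi[:, k] = draw_w()
        return xi
    rho = temporal.rho if temporal.rho is not None else 0.0
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    xi[:, 0] = draw_w() / np.sqrt(1.0 - rho**2)
    for k in range(1, t):
        xi[:, k] = rho * xi[:, k - 1] + draw_w()
    return xi


def simulate_outcomes(
    clusters: pd.DataFrame,
    x_design: np.ndarray,
    beta0: float,
    beta: np.ndarray,
    delta: np.ndarray,
    lam: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Binomial outcomes y ~ Bin(n, expit(beta0 + X beta + delta + lambda))."""
    rng = np.random.default_rng(seed)
    n = clusters["n"].to_numpy()
    if (n == 0).any():
        warnings.warn(f"{int((n == 0).sum())} clusters with n = 0 skipped")
    eta = beta0 + np.asarray(x_design, float) @ np.asarray(beta, float) + delta + lam
    p = expit(eta)
    y = np.where(n > 0, rng.binomial(np.maximum(n, 1), p), 0)
    return y


@dataclass
class SyntheticSurvey:
    """A complete simulated survey plus everything needed to score recovery."""

    clusters: pd.DataFrame
    surfaces: dict[str, Raster]
    mesh: Mesh
    field: np.ndarray  # (G, T) latent truth
    lam: np.ndarray  # per-location effect, aligned with unique locations
    config: SimulationConfig

    @property
    def truth(self) -> dict[str, float]:
        cfg = self.config
        return {
            "beta0": cfg.beta0,
            **{f"beta_{n}": b for n, b in zip(cfg.covariate_names, cfg.beta)},
            "sigma2_sp": spatial_variance(cfg.spde),
            "range_km": cfg.spde.range_km,
            "sigma2_nonsp": cfg.sigma2_nonsp,
            "rho": cfg.rho if cfg.temporal_mode == "ar1" else 0.0,
        }


def simulate_survey(config: SimulationConfig, mesh: Mesh | None = None) -> SyntheticSurvey:
    """End-to-end generation: surfaces, clusters, field, outcomes.

    Covariates are extracted from the surfaces at the *true* coordinates
    (so the covariate effect truth is exact), then standardized; the
    returned table also carries the displaced coordinates that a real
    analysis would see.
    """
    from .preprocess import extract_at_points, standardize
    from .spde import build_mesh, projection_matrix

    surfaces = gen_covariate_surfaces(config)
    clusters = sample_clusters(config)
    pts_true = clusters[["x_true", "y_true"]].to_numpy()

    for name in config.covariate_names:
        raw = extract_at_points(surfaces[name], pts_true)
        if np.unique(raw).size < 2:  # constant surface (infinite smoothness)
            clusters[name] = 0.0
        else:
            clusters[name], _ = standardize(raw, name)

    if mesh is None:
        extent = config.spde.range_km
        mesh = build_mesh(
            pts_true, max_edge=extent / 2.0, cutoff=1e-6, extension=extent
        )
    xi = simulate_field(mesh, config.spde, config.temporal, seed=config.seed + 2)
    a_mat = projection_matrix(mesh, pts_true)
    knots = config.temporal.knots
    w_time = np.vstack(
        [temporal_projection(yr, knots) for yr in clusters["year"].to_numpy()]
    )  # (n_obs, T)
    delta = np.einsum("ik,ik->i", np.asarray(a_mat @ xi), w_time)

    rng = np.random.default_rng(config.seed + 3)
    locations = clusters["cluster_id"].unique()
    lam_by_loc = rng.normal(0.0, np.sqrt(config.sigma2_nonsp), size=len(locations))
    loc_index = {c: i for i, c in enumerate(locations)}
    lam = lam_by_loc[[loc_index[c] for c in clusters["cluster_id"]]]

    x_design = clusters[config.covariate_names].to_numpy()
    clusters["y"] = simulate_outcomes(
        clusters,
        x_design,
        config.beta0,
        np.asarray(config.beta),
        delta,
        lam,
        seed=config.seed + 4,
    )
    clusters["p_true"] = expit(
        config.beta0 + x_design @ np.asarray(config.beta) + delta + lam
    )
    return SyntheticSurvey(
        clusters=clusters,
        surfaces=surfaces,
        mesh=mesh,
        field=xi,
        lam=lam_by_loc,
        config=config,
    )
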