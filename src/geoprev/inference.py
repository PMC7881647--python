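"""Posterior computation for the hierarchical logit-binomial model.

Sampling strategy
-----------------
The latent Gaussian block u = (beta0, beta, lambda, xi) is constrained by
B u = 0 (design orthogonality, integrate-to-zero per knot, sum-to-zero on
lambda).  We reparameterize u = Z v with Z an orthonormal basis of the null
space of B, so every draw satisfies the constraints to machine precision,
and run an exact Metropolis-Hastings scheme on (theta, v):

* hyperparameters move by covariance-adaptive random-walk proposals on
  (log sigma2_sp, log range, transformed rho, log precision of lambda),
  jointly with a *deterministic Gaussian transport* of the current latent
  state between the Laplace (Gaussian) approximations of p(v | y, theta)
  at the current and proposed theta — a triangular-map change of variables
  whose Jacobian enters the MH ratio, so theta moves are not throttled by
  latent resampling noise;
* an independence refresh of v from the cached Laplace approximation runs
  every iteration and keeps the latent block ergodic.

The Laplace approximation is exact for Gaussian likelihoods and extremely
close for binomial counts at survey sample sizes; the MH correction keeps
the chain exactly invariant for the true posterior.  All adaptation is
frozen after warm-up.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import expit

from .model import (
    PriorSpec,
    TemporalSpec,
    ar1_innovation_precision,
    log_likelihood,
    log_prior,
    temporal_projection,
)
from .preprocess import standardize
from .spde import Mesh, SPDEParams, build_mesh, projection_matrix, spde_precision
from .spde import fem_matrices

__all__ = [
    "ModelSpec",
    "SamplerConfig",
    "PosteriorResult",
    "fit",
    "posterior_summary",
    "posterior_linpred",
    "decide_temporal_mode",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``forms`` maps covariate name to 'linear' (standardized) or
    'categorical3' (tertile dummies, lowest level as baseline).
    """

    covariates: tuple[str, ...] = ()
    forms: dict | None = None
    temporal: TemporalSpec = TemporalSpec(knots=(2007.0, 2010.5, 2014.0), mode="ar1", rho=0.4)
    use_field: bool = True
    use_lambda: bool = True
    nu: float = 1.0
    priors: PriorSpec = PriorSpec()
    mesh_max_edge: float | None = None
    mesh_extension: float | None = None

    def form_of(self, name: str) -> str:
        return (self.forms or {}).get(name, "linear")


@dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 2
    n_warmup: int = 500
    n_keep: int = 1000
    seed: int = 0
    step_init: float = 0.25
    target_accept: float = 0.30
    max_newton: int = 50


# --------------------------------------------------------------------------
# model structure (design, mesh, constraints)
# --------------------------------------------------------------------------


@dataclass
class ModelStructure:
    """Everything derived from data + spec that the sampler and predictors need."""

    spec: ModelSpec
    y: np.ndarray
    n: np.ndarray
    x_design: np.ndarray  # (n_obs, p) without intercept
    design_names: list[str]
    scalers: dict
    tertile_cuts: dict
    loc_index: np.ndarray | None  # lambda index per observation
    n_loc: int
    mesh: Mesh | None
    a_st: sp.csr_matrix | None  # (n_obs, G*T) space-time projection
    mass_diag: np.ndarray | None
    fem_g: sp.csc_matrix | None  # cached stiffness matrix
    z_basis: np.ndarray  # (n_u, m) null-space basis of the constraints
    b_matrix: np.ndarray  # (k, n_u)
    m_design: sp.csr_matrix  # (n_obs, n_u) latent-to-linear-predictor map
    mz: np.ndarray  # dense M @ Z

    @property
    def n_beta(self) -> int:
        return self.x_design.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_vertices if self.mesh is not None else 0

    @property
    def n_knots(self) -> int:
        return self.spec.temporal.n_knots

    def slices(self):
        p = self.n_beta
        n_lam = self.n_loc
        n_xi = self.n_vertices * self.n_knots if self.mesh is not None else 0
        s_beta0 = slice(0, 1)
        s_beta = slice(1, 1 + p)
        s_lam = slice(1 + p, 1 + p + n_lam)
        s_xi = slice(1 + p + n_lam, 1 + p + n_lam + n_xi)
        return s_beta0, s_beta, s_lam, s_xi

    @property
    def n_latent(self) -> int:
        _, _, _, s_xi = self.slices()
        return s_xi.stop


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], dict, dict]:
    """Design matrix (no intercept) with per-column provenance."""
    cols, names = [], []
    scalers: dict = {}
    cuts: dict = {}
    for name in spec.covariates:
        raw = data[name].to_numpy(dtype=float)
        if spec.form_of(name) == "categorical3":
            q1, q2 = np.quantile(raw, [1 / 3, 2 / 3])
            if q1 == q2:
                raise ValueError(f"tertile ties for covariate {name!r}")
            codes = np.digitize(raw, [q1, q2])
            cuts[name] = (float(q1), float(q2))
            for level in (1, 2):
                cols.append((codes == level).astype(float))
                names.append(f"{name}[T{level}]")
        else:
            std, scaler = standardize(raw, name)
            scalers[name] = scaler
            cols.append(std)
            names.append(name)
    x = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return x, names, scalers, cuts


def build_structure(
    data: pd.DataFrame,
    spec: ModelSpec,
    mesh: Mesh | None = None,
) -> ModelStructure:
    y = data["y"].to_numpy(dtype=float)
    n = data["n"].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= y <= n")
    if len(data) < 2:
        raise ValueError("need at least 2 clusters")
    x, names, scalers, cuts = build_design(data, spec)
    x_full = np.column_stack([np.ones(len(data)), x])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("design matrix is rank deficient")

    if spec.use_lambda:
        codes, uniques = pd.factorize(data["cluster_id"])
        loc_index = codes.astype(int)
        n_loc = len(uniques)
    else:
        loc_index, n_loc = None, 0

    a_st = None
    mass_diag = None
    if spec.use_field:
        pts = data[["x_km", "y_km"]].to_numpy()
        if mesh is None:
            span = np.ptp(pts, axis=0)
            diag = float(np.hypot(*span)) or 1.0
            max_edge = spec.mesh_max_edge or diag / 8.0
            extension = spec.mesh_extension or diag / 6.0
            mesh = build_mesh(pts, max_edge=max_edge, cutoff=1e-6, extension=extension)
        a_sp = projection_matrix(mesh, pts)  # (n_obs, G)
        t_knots = spec.temporal.knots
        w_time = np.vstack(
            [temporal_projection(yr, t_knots) for yr in data["year"].to_numpy()]
        )
        # vertex-major kron rows: row_i = kron(a_sp_i, w_time_i)
        a_st = sp.hstack(
            [
                a_sp.multiply(w_time[:, [t]])
                for t in range(len(t_knots))
            ],
            format="csr",
        )
        # reorder columns from knot-major blocks to vertex-major interleave
        g = mesh.n_vertices
        t = len(t_knots)
        perm = np.arange(g * t).reshape(t, g).T.ravel()
        a_st = a_st[:, perm].tocsr()
        c_mat, fem_g = fem_matrices(mesh)
        mass_diag = c_mat.diagonal()
    else:
        mesh = None
        fem_g = None

    # latent-to-eta map M = [1 | X | Lambda | A_st]
    blocks = [sp.csr_matrix(np.ones((len(data), 1))), sp.csr_matrix(x)]
    if spec.use_lambda:
        lam_map = sp.coo_matrix(
            (np.ones(len(data)), (np.arange(len(data)), loc_index)),
            shape=(len(data), n_loc),
        ).tocsr()
        blocks.append(lam_map)
    if spec.use_field:
        blocks.append(a_st)
    m_design = sp.hstack(blocks, format="csr")

    # constraints
    n_u = m_design.shape[1]
    p = x.shape[1]
    rows = []
    off_lam = 1 + p
    off_xi = off_lam + n_loc
    if spec.use_lambda and n_loc > 1:
        row = np.zeros(n_u)
        row[off_lam:off_xi] = 1.0
        rows.append(row)
    if spec.use_field:
        g = mesh.n_vertices
        t = spec.temporal.n_knots
        # orthogonality of the projected field to [1, X]
        q_x, _ = np.linalg.qr(x_full)
        orth = q_x.T @ a_st.toarray()  # (p+1, G*T)
        for r in orth:
            row = np.zeros(n_u)
            row[off_xi:] = r
            rows.append(row)
        # integrate-to-zero per knot (mass-weighted vertex sum)
        for knot in range(t):
            row = np.zeros(n_u)
            row[off_xi + knot :: t] = mass_diag
            rows.append(row)
    if rows:
        b_matrix = np.vstack(rows)
        # drop numerically dependent rows (e.g. orthogonality vs integrate rows)
        q_r, r_r = np.linalg.qr(b_matrix.T)
        keep = np.abs(np.diag(r_r)) > 1e-10 * np.abs(np.diag(r_r)).max()
        b_matrix = b_matrix[keep]
        from scipy.linalg import null_space

        z_basis = null_space(b_matrix)
    else:
        b_matrix = np.empty((0, n_u))
        z_basis = np.eye(n_u)

    mz = np.asarray(m_design @ z_basis)
    return ModelStructure(
        spec=spec,
        y=y,
        n=n,
        x_design=x,
        design_names=names,
        scalers=scalers,
        tertile_cuts=cuts,
        loc_index=loc_index,
        n_loc=n_loc,
        mesh=mesh,
        a_st=a_st,
        mass_diag=mass_diag,
        fem_g=fem_g,
        z_basis=z_basis,
        b_matrix=b_matrix,
        m_design=m_design,
        mz=mz,
    )


# --------------------------------------------------------------------------
# hyperparameter bookkeeping
# --------------------------------------------------------------------------


class _ThetaMap:
    """Maps the active hyperparameters to/from the sampling parameterization.

    The field block is sampled as (log sigma2_sp, log range) — the scales the
    data identify directly, which decorrelates the random walk — and mapped
    back to (log kappa, log tau), where the stated priors live.  The map is
    linear, so its Jacobian is constant and drops out of the MH ratio.
    """

    def __init__(self, spec: ModelSpec):
        self.nu = spec.nu
        self.names: list[str] = []
        if spec.use_field:
            self.names += ["log_sigma2", "log_range"]
            if spec.temporal.mode == "ar1":
                self.names.append("z_rho")
        if spec.use_lambda:
            self.names.append("log_prec_lambda")
        self.size = len(self.names)

    def unpack(self, theta: np.ndarray) -> dict:
        out = dict(zip(self.names, theta))
        if "log_range" in out:
            nu = self.nu
            log_kappa = 0.5 * np.log(8.0 * nu) - out["log_range"]
            # sigma2 = G(nu)/(G(nu+1) 4 pi kappa^(2nu) tau^2)
            from scipy.special import gammaln

            log_tau = 0.5 * (
                gammaln(nu)
                - gammaln(nu + 1.0)
                - np.log(4.0 * np.pi)
                - 2.0 * nu * log_kappa
                - out["log_sigma2"]
            )
            out["log_kappa"] = float(log_kappa)
            out["log_tau"] = float(log_tau)
        if "z_rho" in out:
            out["rho"] = float(np.tanh(out["z_rho"] / 2.0))
        return out

    def unpack_arrays(self, theta_all: np.ndarray) -> dict:
        """Vectorized unpack over an (S, size) array of kept draws."""
        cols = {name: theta_all[:, j] for j, name in enumerate(self.names)}
        out: dict = {}
        if "log_range" in cols:
            from scipy.special import gammaln

            nu = self.nu
            log_kappa = 0.5 * np.log(8.0 * nu) - cols["log_range"]
            log_tau = 0.5 * (
                gammaln(nu)
                - gammaln(nu + 1.0)
                - np.log(4.0 * np.pi)
                - 2.0 * nu * log_kappa
                - cols["log_sigma2"]
            )
            out["kappa"] = np.exp(log_kappa)
            out["tau"] = np.exp(log_tau)
            out["sigma2_sp"] = np.exp(cols["log_sigma2"])
            out["range_km"] = np.exp(cols["log_range"])
        if "z_rho" in cols:
            out["rho"] = np.tanh(cols["z_rho"] / 2.0)
        if "log_prec_lambda" in cols:
            out["sigma2_nonsp"] = np.exp(-cols["log_prec_lambda"])
        return out


def _prior_precision(
    struct: ModelStructure, params: dict, prior: PriorSpec
) -> sp.csc_matrix:
    spec = struct.spec
    blocks = [sp.diags(np.full(1 + struct.n_beta, 1.0 / prior.beta_var))]
    if spec.use_lambda:
        blocks.append(sp.diags(np.full(struct.n_loc, np.exp(params["log_prec_lambda"]))))
    if spec.use_field:
        kappa = float(np.exp(params["log_kappa"]))
        tau = float(np.exp(params["log_tau"]))
        if spec.nu == 1.0 and struct.fem_g is not None:
            # exact order-2 assembly from cached FEM matrices
            k_mat = sp.diags(kappa**2 * struct.mass_diag) + struct.fem_g
            c_inv = sp.diags(1.0 / struct.mass_diag)
            q_s = (tau**2) * (k_mat @ c_inv @ k_mat)
            q_s = ((q_s + q_s.T) * 0.5).tocsc()
        else:
            q_s = spde_precision(
                struct.mesh, SPDEParams(kappa=kappa, tau=tau, nu=spec.nu)
            )
        t = spec.temporal.n_knots
        if spec.temporal.mode == "ar1":
            q_t = ar1_innovation_precision(t, params["rho"])
        else:
            q_t = np.eye(t)
        blocks.append(sp.kron(q_s, sp.csc_matrix(q_t)))
    return sp.block_diag(blocks, format="csc")


def _theta_log_prior(params: dict, prior: PriorSpec, spec: ModelSpec) -> float:
    total = 0.0
    if spec.use_field:
        total += log_prior(
            prior,
            log_tau=params["log_tau"],
            log_kappa=params["log_kappa"],
        )
        if spec.temporal.mode == "ar1":
            # prior stated on z = log((1+rho)/(1-rho)); our chain moves z_rho
            # directly, so use the z-scale density without a Jacobian
            var = prior.rho_trans_var
            z = params["z_rho"]
            total += -0.5 * (np.log(2 * np.pi * var) + (z - prior.rho_trans_mean) ** 2 / var)
    if spec.use_lambda:
        # gamma(shape, rate) on the precision, plus log-scale Jacobian
        prec = np.exp(params["log_prec_lambda"])
        total += log_prior(prior, nonsp_precision=prec) + params["log_prec_lambda"]
    return float(total)


# --------------------------------------------------------------------------
# Laplace approximation machinery
# --------------------------------------------------------------------------


class _Laplace:
    """Gaussian approximation of p(v | y, theta) and its factorization."""

    __slots__ = ("v_hat", "chol_h", "logdet_h", "pz", "chol_pz_logdet")

    def __init__(self, v_hat, chol_h, logdet_h, pz, chol_pz_logdet):
        self.v_hat = v_hat
        self.chol_h = chol_h
        self.logdet_h = logdet_h
        self.pz = pz
        self.chol_pz_logdet = chol_pz_logdet


def _loglik_eta(struct: ModelStructure, eta: np.ndarray) -> float:
    return log_likelihood(struct.y, struct.n, eta)


def _laplace(
    struct: ModelStructure,
    pz: np.ndarray,
    v0: np.ndarray | None,
    max_newton: int,
) -> _Laplace:
    mz = struct.mz
    y, n = struct.y, struct.n
    m = pz.shape[0]
    v = np.zeros(m) if v0 is None else v0.copy()

    chol_pz = cholesky(pz, lower=True)
    logdet_pz = 2.0 * float(np.sum(np.log(np.diag(chol_pz))))

    def objective(vv):
        return _loglik_eta(struct, mz @ vv) - 0.5 * float(vv @ pz @ vv)

    f_cur = objective(v)
    chol_h = None
    for _ in range(max_newton):
        eta = mz @ v
        p = expit(eta)
        w = np.maximum(n * p * (1.0 - p), 1e-10)
        grad = mz.T @ (y - n * p) - pz @ v
        h = (mz * w[:, None]).T @ mz + pz
        chol_h = cho_factor(h, lower=True)
        step = cho_solve(chol_h, grad)
        # backtracking line search
        t_step = 1.0
        for _ in range(30):
            v_new = v + t_step * step
            f_new = objective(v_new)
            if f_new >= f_cur - 1e-12:
                break
            t_step *= 0.5
        if f_new < f_cur:
            break
        converged = f_new - f_cur < 1e-7 * (1.0 + abs(f_cur))
        v, f_cur = v_new, f_new
        if converged:
            break
    # final Hessian at the mode
    eta = mz @ v
    p = expit(eta)
    w = np.maximum(n * p * (1.0 - p), 1e-10)
    h = (mz * w[:, None]).T @ mz + pz
    chol_h = cholesky(h, lower=True)
    logdet_h = 2.0 * float(np.sum(np.log(np.diag(chol_h))))
    return _Laplace(v, chol_h, logdet_h, pz, logdet_pz)


def _proposal_draw(lap: _Laplace, rng) -> tuple[np.ndarray, float]:
    z = rng.standard_normal(lap.v_hat.size)
    v = lap.v_hat + solve_triangular(lap.chol_h.T, z, lower=False)
    logq = 0.5 * lap.logdet_h - 0.5 * float(z @ z)
    return v, logq


def _proposal_logq(lap: _Laplace, v: np.ndarray) -> float:
    d = lap.chol_h.T @ (v - lap.v_hat)
    return 0.5 * lap.logdet_h - 0.5 * float(d @ d)


def _log_target_v(struct: ModelStructure, lap: _Laplace, v: np.ndarray) -> float:
    """log p(y | v) + log p(v | theta) up to theta-independent constants."""
    return (
        _loglik_eta(struct, struct.mz @ v)
        - 0.5 * float(v @ lap.pz @ v)
        + 0.5 * lap.chol_pz_logdet
    )


# --------------------------------------------------------------------------
# results container
# --------------------------------------------------------------------------


@dataclass
class PosteriorResult:
    draws: dict  # name -> (S,) or (S, dim) arrays, chains concatenated
    chain_ids: np.ndarray
    structure: ModelStructure
    diagnostics: dict
    seed: int
    config_hash: str

    def summary(self, name: str) -> tuple[float, float, float]:
        return posterior_summary(self, name)

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            arr = np.atleast_2d(np.asarray(arr).T).T
            if arr.ndim > 1 and arr.shape[1] > 20:
                continue  # skip bulky latent blocks in the flat table
            labels = (
                [name]
                if arr.ndim == 1 or arr.shape[1] == 1
                else [f"{name}[{j}]" for j in range(arr.shape[1])]
            )
            cols = arr if arr.ndim > 1 else arr[:, None]
            for j, label in enumerate(labels):
                lo, med, hi = np.percentile(cols[:, j], [2.5, 50.0, 97.5])
                rows.append(
                    {
                        "parameter": label,
                        "median": med,
                        "q2.5": lo,
                        "q97.5": hi,
                        "significant": bool(lo > 0 or hi < 0),
                    }
                )
        return pd.DataFrame(rows)


def posterior_summary(result: PosteriorResult, name: str):
    """(median, 2.5%, 97.5%) empirical quantiles of a scalar quantity.

    The significance convention follows the '95% BCI excludes zero' rule.
    """
    draws = np.asarray(result.draws[name])
    if draws.ndim > 1:
        raise ValueError(f"{name!r} is vector-valued; index it first")
    if draws.size < 100:
        raise ValueError("need at least 100 draws for stable quantiles")
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return float(med), float(lo), float(hi)


def _ess(x: np.ndarray) -> float:
    """Effective sample size from pairwise-sum autocorrelations (Geyer)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.ptp(x) == 0:
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var())
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def _split_rhat(chains: list[np.ndarray]) -> float:
    halves = []
    for c in chains:
        h = len(c) // 2
        if h >= 2:
            halves += [c[:h], c[h : 2 * h]]
    if len(halves) < 2:
        return 1.0
    halves = np.array(halves)
    mchain = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    b = len(halves[0]) * mchain.var(ddof=1)
    var_plus = (len(halves[0]) - 1) / len(halves[0]) * w + b / len(halves[0])
    return float(np.sqrt(var_plus / w))


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------


def _run_chain(
    struct: ModelStructure,
    sampler: SamplerConfig,
    theta_map: _ThetaMap,
    theta0: np.ndarray,
    seed: int,
) -> dict:
    rng = np.random.default_rng(seed)
    spec = struct.spec
    prior = spec.priors
    n_iter = sampler.n_warmup + sampler.n_keep

    theta = theta0.copy()
    params = theta_map.unpack(theta)
    pz = struct.z_basis.T @ (
        _prior_precision(struct, params, prior) @ struct.z_basis
    )
    lap = _laplace(struct, pz, None, sampler.max_newton)
    v, _ = _proposal_draw(lap, rng)
    log_post_v = _log_target_v(struct, lap, v)
    lp_theta = _theta_log_prior(params, prior, spec)

    step = sampler.step_init
    prop_chol = np.eye(theta_map.size) if theta_map.size else None
    warm_thetas: list[np.ndarray] = []
    acc_theta = 0
    acc_latent = 0
    n_theta_updates = 0

    keep_v = np.empty((sampler.n_keep, v.size))
    keep_theta = np.empty((sampler.n_keep, theta_map.size))

    for it in range(n_iter):
        # ---- joint (theta, v) update -------------------------------------
        if theta_map.size:
            n_theta_updates += 1
            theta_prop = theta + step * (prop_chol @ rng.standard_normal(theta_map.size))
            params_prop = theta_map.unpack(theta_prop)
            pz_prop = struct.z_basis.T @ (
                _prior_precision(struct, params_prop, prior) @ struct.z_basis
            )
            try:
                lap_prop = _laplace(struct, pz_prop, lap.v_hat, sampler.max_newton)
            except np.linalg.LinAlgError:
                lap_prop = None
            alpha_now = 0.0
            if lap_prop is not None:
                # deterministic Gaussian transport of the current latent state
                # between the Laplace approximations at theta and theta*:
                # v* = vhat* + L*^-T L^T (v - vhat), log|J| = (logdetH - logdetH*)/2
                w = lap.chol_h.T @ (v - lap.v_hat)
                v_prop = lap_prop.v_hat + solve_triangular(
                    lap_prop.chol_h.T, w, lower=False
                )
                log_jac = 0.5 * (lap.logdet_h - lap_prop.logdet_h)
                lp_theta_prop = _theta_log_prior(params_prop, prior, spec)
                log_post_prop = _log_target_v(struct, lap_prop, v_prop)
                log_alpha = (
                    log_post_prop
                    + lp_theta_prop
                    + log_jac
                    - (log_post_v + lp_theta)
                )
                alpha_now = float(np.exp(min(log_alpha, 0.0)))
                if np.log(rng.uniform()) < log_alpha:
                    theta, params, lap, v = theta_prop, params_prop, lap_prop, v_prop
                    log_post_v = log_post_prop
                    lp_theta = lp_theta_prop
                    acc_theta += 1
            if it < sampler.n_warmup:
                # Robbins-Monro on the *current* acceptance probability
                gamma = 1.0 / (1.0 + it) ** 0.6
                step *= np.exp(gamma * (alpha_now - sampler.target_accept))
                warm_thetas.append(theta.copy())
                # covariance adaptation handles the (sigma2, range) ridge
                if len(warm_thetas) >= 100 and len(warm_thetas) % 50 == 0:
                    emp = np.cov(np.asarray(warm_thetas[-400:]).T)
                    emp = np.atleast_2d(emp) + 1e-6 * np.eye(theta_map.size)
                    try:
                        prop_chol = np.linalg.cholesky(emp)
                    except np.linalg.LinAlgError:
                        pass

        # ---- latent refresh at current theta -----------------------------
        v_prop, logq_prop = _proposal_draw(lap, rng)
        log_post_prop = _log_target_v(struct, lap, v_prop)
        logq_cur = _proposal_logq(lap, v)
        if np.log(rng.uniform()) < (log_post_prop - logq_prop) - (
            log_post_v - logq_cur
        ):
            v = v_prop
            log_post_v = log_post_prop
            acc_latent += 1

        if it >= sampler.n_warmup:
            keep_v[it - sampler.n_warmup] = v
            keep_theta[it - sampler.n_warmup] = theta

    if theta_map.size and acc_theta / max(n_theta_updates, 1) < 0.01:
        raise RuntimeError(
            "sampler diverged: hyperparameter acceptance below 1% "
            f"({acc_theta}/{n_theta_updates})"
        )
    return {
        "v": keep_v,
        "theta": keep_theta,
        "accept_theta": acc_theta / max(n_theta_updates, 1),
        "accept_latent": acc_latent / n_iter,
    }


def _initial_theta(struct: ModelStructure, theta_map: _ThetaMap) -> np.ndarray:
    out = []
    for name in theta_map.names:
        if name == "log_sigma2":
            out.append(np.log(0.2))
        elif name == "log_range":
            pts = struct.mesh.vertices
            diag = float(np.hypot(*np.ptp(pts, axis=0)))
            out.append(np.log(0.25 * diag))
        elif name == "z_rho":
            out.append(0.0)
        elif name == "log_prec_lambda":
            out.append(np.log(10.0))
    return np.array(out)


def fit(
    data: pd.DataFrame,
    spec: ModelSpec,
    sampler: SamplerConfig | None = None,
    mesh: Mesh | None = None,
) -> PosteriorResult:
    """Run the blocked MCMC and return draws, summaries and diagnostics.

    ``data`` needs columns cluster_id, year, x_km, y_km, n, y plus the
    covariates named in ``spec``.  Identical data + spec + sampler seed give
    bit-identical chains.
    """
    sampler = sampler or SamplerConfig()
    struct = build_structure(data, spec, mesh=mesh)
    theta_map = _ThetaMap(spec)
    theta0 = _initial_theta(struct, theta_map)

    chain_results = []
    for c in range(sampler.n_chains):
        chain_results.append(
            _run_chain(struct, sampler, theta_map, theta0, seed=sampler.seed + 1000 * c)
        )

    v_all = np.vstack([r["v"] for r in chain_results])
    theta_all = np.vstack([r["theta"] for r in chain_results])
    chain_ids = np.repeat(np.arange(sampler.n_chains), sampler.n_keep)
    u_all = v_all @ struct.z_basis.T  # (S, n_u)

    s_beta0, s_beta, s_lam, s_xi = struct.slices()
    draws: dict = {
        "beta0": u_all[:, s_beta0].ravel(),
        "beta": u_all[:, s_beta],
        "lambda": u_all[:, s_lam],
        "xi": u_all[:, s_xi],
    }
    hyper_draws = theta_map.unpack_arrays(theta_all)
    draws.update(hyper_draws)
    hyper_names = list(hyper_draws)

    # constraint satisfaction of retained draws (checked inline)
    if struct.b_matrix.shape[0]:
        viol = float(np.max(np.abs(struct.b_matrix @ u_all.T)))
    else:
        viol = 0.0
    lam_sums = (
        float(np.max(np.abs(u_all[:, s_lam].sum(axis=1)))) if spec.use_lambda else 0.0
    )

    diagnostics: dict = {
        "accept_theta": float(np.mean([r["accept_theta"] for r in chain_results])),
        "accept_latent": float(np.mean([r["accept_latent"] for r in chain_results])),
        "max_constraint_violation": viol,
        "max_lambda_sum": lam_sums,
        "ess": {},
        "rhat": {},
    }
    for name in hyper_names + ["beta0"]:
        series = np.asarray(draws[name], dtype=float)
        per_chain = [
            series[chain_ids == c] for c in range(sampler.n_chains)
        ]
        diagnostics["ess"][name] = float(np.sum([_ess(s) for s in per_chain]))
        diagnostics["rhat"][name] = _split_rhat(per_chain)

    cfg_repr = json.dumps(
        {
            "covariates": list(spec.covariates),
            "temporal": [list(spec.temporal.knots), spec.temporal.mode],
            "sampler": [sampler.n_chains, sampler.n_warmup, sampler.n_keep, sampler.seed],
        },
        sort_keys=True,
    )
    return PosteriorResult(
        draws=draws,
        chain_ids=chain_ids,
        structure=struct,
        diagnostics=diagnostics,
        seed=sampler.seed,
        config_hash=hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
    )


# --------------------------------------------------------------------------
# prediction and the temporal-mode rule
# --------------------------------------------------------------------------


def posterior_linpred(
    result: PosteriorResult,
    points: np.ndarray,
    x_new: np.ndarray,
    year: float,
    include_lambda_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Posterior draws of the linear predictor at new locations, shape (S, n).

    ``x_new`` must be on the same (already standardized / dummy-coded) scale
    as the fitted design.  The location effect lambda is excluded at new
    locations by default; ``include_lambda_noise`` adds fresh
    N(0, sigma2_nonsp) draws instead.
    """
    struct = result.structure
    spec = struct.spec
    s_draws = result.draws
    n_s = s_draws["beta0"].size
    eta = s_draws["beta0"][:, None] + s_draws["beta"] @ np.atleast_2d(x_new).T
    if spec.use_field:
        a_sp = projection_matrix(struct.mesh, points)
        w_t = temporal_projection(year, spec.temporal.knots)
        g = struct.mesh.n_vertices
        t = spec.temporal.n_knots
        xi = s_draws["xi"].reshape(n_s, g, t)
        field_at_knots = np.einsum("sgt,t->sg", xi, w_t)
        eta = eta + field_at_knots @ a_sp.T.toarray()
    if include_lambda_noise and spec.use_lambda:
        rng = rng or np.random.default_rng(0)
        sd = np.sqrt(s_draws["sigma2_nonsp"])
        eta = eta + sd[:, None] * rng.standard_normal(eta.shape)
    return eta


def decide_temporal_mode(result: PosteriorResult) -> str:
    """'exchangeable' iff the 95% BCI of rho contains zero (ties included)."""
    if "rho" not in result.draws:
        return "exchangeable"
    lo, hi = np.percentile(result.draws["rho"], [2.5, 97.5])
    return "exchangeable" if lo <= 0.0 <= hi else "ar1"
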