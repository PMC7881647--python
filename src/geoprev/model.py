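"""Hierarchical logit-binomial space-time model components.

The observation model is

    Y_it ~ Binomial(n_it, p_it)
    logit(p_it) = beta0 + X_it' beta + delta_it + lambda_i

with ``delta`` a separable space-time Gauss-Markov field on mesh vertices x
time knots (precision a Kronecker product of a spatial SPDE precision and a
temporal AR1/exchangeable precision) and ``lambda`` an i.i.d. location-level
effect.  Identification uses three linear constraint families: orthogonality
of the projected field to the fixed-effect design, a per-knot integrate-to-
zero constraint on the field, and a sum-to-zero constraint on ``lambda``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import betaln

__all__ = [
    "TemporalSpec",
    "PriorSpec",
    "ConstraintSet",
    "ar1_precision",
    "ar1_innovation_precision",
    "spacetime_precision",
    "temporal_projection",
    "log_likelihood",
    "log_prior",
    "build_constraints",
    "apply_constraints",
]


@dataclass(frozen=True)
class TemporalSpec:
    """Time-knot layout and temporal dependence mode."""

    knots: tuple[float, ...]
    mode: str = "ar1"  # "ar1" | "exchangeable"
    rho: float | None = None

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        object.__setattr__(self, "knots", knots)
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError("knots must be strictly increasing")
        if self.mode not in ("ar1", "exchangeable"):
            raise ValueError("mode must be 'ar1' or 'exchangeable'")
        if self.mode == "ar1" and len(knots) > 2:
            gaps = np.diff(knots)
            if not np.allclose(gaps, gaps[0]):
                raise ValueError("ar1 mode requires equally spaced knots")

    @property
    def n_knots(self) -> int:
        return len(self.knots)


def ar1_precision(n_knots: int, rho: float) -> np.ndarray:
    """Inverse of the stationary AR1 *correlation* matrix (unit marginal).

    Tridiagonal; returns the identity for rho = 0 (and for the exchangeable
    mode, which callers encode as rho = 0).
    """
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    if n_knots < 1:
        raise ValueError("need at least one knot")
    if n_knots == 1:
        return np.array([[1.0]])
    q = np.zeros((n_knots, n_knots))
    np.fill_diagonal(q, 1.0 + rho**2)
    if n_knots >= 1:
        q[0, 0] = 1.0
        q[-1, -1] = 1.0
    idx = np.arange(n_knots - 1)
    q[idx, idx + 1] = -rho
    q[idx + 1, idx] = -rho
    return q / (1.0 - rho**2)


def ar1_innovation_precision(n_knots: int, rho: float) -> np.ndarray:
    """AR1 precision under the unit-*innovation* convention.

    Corresponds to xi_t = rho xi_{t-1} + w_t with Var(w) = 1 and stationary
    start Var(xi_1) = 1/(1 - rho^2); equals (1 - rho^2) times
    :func:`ar1_precision`.  This is the scaling used when the innovations
    carry the spatial variance.
    """
    return (1.0 - rho**2) * ar1_precision(n_knots, rho)


def spacetime_precision(q_s: sp.spmatrix, q_t: np.ndarray) -> sp.csc_matrix:
    """Separable space-time precision Q = Qs (x) Qt.

    Field ordering is vertex-major: entry ``g * T + t`` holds vertex g at
    knot t.
    """
    q_s = sp.csc_matrix(q_s)
    q_t = np.asarray(q_t, dtype=float)
    if q_t.ndim != 2 or q_t.shape[0] != q_t.shape[1]:
        raise ValueError("Qt must be square")
    if (abs(q_s - q_s.T) > 1e-10 * abs(q_s).max()).nnz:
        raise ValueError("Qs must be symmetric")
    return sp.kron(q_s, sp.csc_matrix(q_t), format="csc")


def temporal_projection(year: float, knots) -> np.ndarray:
    """Degree-one B-spline (linear interpolation) weights over the knots.

    Weights are nonnegative, sum to one, and reduce to an indicator at a
    knot.  Years outside the knot span raise (no extrapolation).
    """
    knots = np.asarray(knots, dtype=float)
    if year < knots[0] or year > knots[-1]:
        raise ValueError(f"year {year} outside knot span [{knots[0]}, {knots[-1]}]")
    w = np.zeros(knots.size)
    j = int(np.searchsorted(knots, year, side="right")) - 1
    if j == knots.size - 1:
        w[-1] = 1.0
        return w
    frac = (year - knots[j]) / (knots[j + 1] - knots[j])
    w[j] = 1.0 - frac
    w[j + 1] = frac
    return w


def log_likelihood(y, n, eta) -> float:
    """Binomial log-likelihood at linear predictor eta (logit scale).

    Includes the binomial coefficient so values are comparable across
    models; matches a direct sum of ``binom.logpmf`` terms.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= y <= n")
    log_binom = -betaln(1.0 + y, 1.0 + n - y) - np.log(n + 1.0)
    # y*eta - n*log(1+exp(eta)), computed stably
    return float(np.sum(log_binom + y * eta - n * np.logaddexp(0.0, eta)))


@dataclass(frozen=True)
class PriorSpec:
    """Hyperprior settings.

    Second parameters of the normal priors follow the configured convention:
    ``variance`` (default, matching "distributions with large variances")
    for beta0/beta/log tau/log kappa, while the AR1 transform
    log((1+rho)/(1-rho)) ~ N(0, 0.15) reads 0.15 as a *precision* (the
    conventional vague choice); both are switchable.
    """

    beta_var: float = 1000.0
    log_tau_mean: float = 0.378
    log_tau_var: float = 10.0
    log_kappa_mean: float = -1.64
    log_kappa_var: float = 10.0
    rho_trans_mean: float = 0.0
    rho_trans_second: float = 0.15
    rho_second_is_precision: bool = True
    nonsp_prec_shape: float = 1.0
    nonsp_prec_rate: float = 0.00005

    @property
    def rho_trans_var(self) -> float:
        if self.rho_second_is_precision:
            return 1.0 / self.rho_trans_second
        return self.rho_trans_second


def _norm_logpdf(x: float, mean: float, var: float) -> float:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def log_prior(
    prior: PriorSpec,
    *,
    beta0: float | None = None,
    beta: np.ndarray | None = None,
    log_tau: float | None = None,
    log_kappa: float | None = None,
    rho: float | None = None,
    nonsp_precision: float | None = None,
) -> float:
    """Sum of the stated log prior densities for the supplied parameters.

    The rho term is evaluated on the transformed scale z = log((1+rho)/(1-rho))
    including the Jacobian dz/drho = 2/(1-rho^2); the non-spatial variance
    prior is gamma(shape, rate) on the precision.
    """
    total = 0.0
    if beta0 is not None:
        total += _norm_logpdf(beta0, 0.0, prior.beta_var)
    if beta is not None:
        for b in np.atleast_1d(beta):
            total += _norm_logpdf(float(b), 0.0, prior.beta_var)
    if log_tau is not None:
        total += _norm_logpdf(log_tau, prior.log_tau_mean, prior.log_tau_var)
    if log_kappa is not None:
        total += _norm_logpdf(log_kappa, prior.log_kappa_mean, prior.log_kappa_var)
    if rho is not None:
        if abs(rho) >= 1:
            return -np.inf
        z = np.log((1.0 + rho) / (1.0 - rho))
        total += _norm_logpdf(z, prior.rho_trans_mean, prior.rho_trans_var)
        total += np.log(2.0 / (1.0 - rho**2))
    if nonsp_precision is not None:
        if nonsp_precision <= 0:
            return -np.inf
        a, r = prior.nonsp_prec_shape, prior.nonsp_prec_rate
        total += a * np.log(r) - math.lgamma(a) + (a - 1.0) * np.log(
            nonsp_precision
        ) - r * nonsp_precision
    return float(total)


@dataclass
class ConstraintSet:
    """Linear constraints B x = 0 on a Gaussian vector with precision Q.

    ``correction`` caches Q^{-1} B' (B Q^{-1} B')^{-1} so that
    :func:`apply_constraints` is a single matrix multiply (conditioning by
    kriging).
    """

    b_matrix: np.ndarray
    correction: np.ndarray

    @property
    def n_constraints(self) -> int:
        return self.b_matrix.shape[0]


def build_constraints(b_matrix: np.ndarray, q: sp.spmatrix) -> ConstraintSet:
    b_matrix = np.atleast_2d(np.asarray(b_matrix, dtype=float))
    if np.linalg.matrix_rank(b_matrix) < b_matrix.shape[0]:
        raise ValueError("constraint rows are rank deficient")
    q = sp.csc_matrix(q)
    qinv_bt = sp.linalg.spsolve(q, sp.csc_matrix(b_matrix.T)).toarray()
    if qinv_bt.ndim == 1:
        qinv_bt = qinv_bt[:, None]
    s_mat = b_matrix @ qinv_bt
    correction = qinv_bt @ np.linalg.inv(s_mat)
    return ConstraintSet(b_matrix=b_matrix, correction=correction)


def apply_constraints(x: np.ndarray, constraints: ConstraintSet) -> np.ndarray:
    """Condition a draw on B x = 0: x - Q^{-1}B'(BQ^{-1}B')^{-1} B x."""
    x = np.asarray(x, dtype=float)
    return x - constraints.correction @ (constraints.b_matrix @ x)
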