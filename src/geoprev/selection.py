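"""Variable selection (DIC / MPL) and k-fold cross-validation."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logsumexp

from .inference import (
    ModelSpec,
    PosteriorResult,
    SamplerConfig,
    fit,
    posterior_linpred,
)
from .spde import Mesh

__all__ = [
    "dic",
    "mpl",
    "select_form",
    "all_subsets",
    "cross_validate",
    "SelectionReport",
    "CVResult",
]

MAX_CANDIDATES = 15


def _u_draws(result: PosteriorResult) -> np.ndarray:
    d = result.draws
    return np.hstack(
        [d["beta0"][:, None], d["beta"], d["lambda"], d["xi"]]
    )


def _pointwise_loglik(result: PosteriorResult) -> np.ndarray:
    """Per-draw, per-observation binomial log-pmf, shape (S, n_obs)."""
    struct = result.structure
    eta = _u_draws(result) @ struct.m_design.T.toarray()  # (S, n_obs)
    y, n = struct.y, struct.n
    log_binom = -betaln(1.0 + y, 1.0 + n - y) - np.log(n + 1.0)
    return log_binom[None, :] + y[None, :] * eta - n[None, :] * np.logaddexp(0.0, eta)


def dic(result: PosteriorResult) -> float:
    """Deviance information criterion.

    DIC = mean deviance + pD with pD = mean deviance minus the deviance at
    the posterior mean of the parameters (latent block included).
    """
    ll = _pointwise_loglik(result)
    if ll.shape[0] < 2:
        raise ValueError("need at least 2 posterior draws")
    dev_draws = -2.0 * ll.sum(axis=1)
    mean_dev = float(dev_draws.mean())

    struct = result.structure
    u_bar = _u_draws(result).mean(axis=0)
    eta_bar = struct.m_design @ u_bar
    y, n = struct.y, struct.n
    log_binom = -betaln(1.0 + y, 1.0 + n - y) - np.log(n + 1.0)
    dev_at_mean = -2.0 * float(
        np.sum(log_binom + y * eta_bar - n * np.logaddexp(0.0, eta_bar))
    )
    p_d = mean_dev - dev_at_mean
    return mean_dev + p_d


def mpl(result: PosteriorResult) -> float:
    """Negative sum of log conditional predictive ordinates (smaller = better).

    CPO_i is approximated by the harmonic mean of the per-draw likelihoods of
    observation i; numerically zero CPOs are flagged with the observation
    indices listed.
    """
    ll = _pointwise_loglik(result)
    if ll.shape[0] < 2:
        raise ValueError("need at least 2 posterior draws")
    s = ll.shape[0]
    log_cpo = np.log(s) - logsumexp(-ll, axis=0)
    bad = ~np.isfinite(log_cpo)
    if bad.any():
        warnings.warn(f"numerically zero CPO at observations {np.where(bad)[0].tolist()}")
        log_cpo = np.where(bad, -745.0, log_cpo)
    return float(-np.sum(log_cpo))


def select_form(
    variable: str,
    data: pd.DataFrame,
    base_spec: ModelSpec,
    sampler: SamplerConfig | None = None,
    mesh: Mesh | None = None,
) -> tuple[str, pd.DataFrame]:
    """Choose linear vs three-level-categorical form for one covariate.

    Fits the two univariate geostatistical models and keeps the form with
    the smaller criterion; DIC arbitrates when DIC and MPL disagree (both
    are recorded in the returned report).
    """
    records = []
    fits = {}
    for form in ("linear", "categorical3"):
        spec = replace(base_spec, covariates=(variable,), forms={variable: form})
        res = fit(data, spec, sampler=sampler, mesh=mesh)
        fits[form] = res
        records.append({"form": form, "dic": dic(res), "mpl": mpl(res)})
    report = pd.DataFrame(records)
    by_dic = report.loc[report["dic"].idxmin(), "form"]
    by_mpl = report.loc[report["mpl"].idxmin(), "form"]
    chosen = by_dic  # DIC wins on disagreement (configured default)
    report["chosen"] = report["form"] == chosen
    report["criteria_agree"] = by_dic == by_mpl
    return chosen, report


@dataclass
class SelectionReport:
    table: pd.DataFrame  # one row per subset with dic, mpl
    chosen: tuple[str, ...]
    final_fit: PosteriorResult | None


def all_subsets(
    candidates: list[str],
    data: pd.DataFrame,
    base_spec: ModelSpec,
    screening_sampler: SamplerConfig | None = None,
    final_sampler: SamplerConfig | None = None,
    mesh: Mesh | None = None,
    refit_final: bool = True,
) -> SelectionReport:
    """Fit every subset of the candidates and rank by DIC (MPL recorded).

    Screening fits use ``screening_sampler`` (short chains); the winning
    subset is refit at ``final_sampler`` settings.
    """
    if len(candidates) > MAX_CANDIDATES:
        raise ValueError(
            f"{len(candidates)} candidates exceed the 2^k guard rail "
            f"({MAX_CANDIDATES}); prune the list first"
        )
    rows = []
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            spec = replace(base_spec, covariates=subset)
            res = fit(data, spec, sampler=screening_sampler, mesh=mesh)
            rows.append({"subset": subset, "size": size, "dic": dic(res), "mpl": mpl(res)})
    table = pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
    chosen = tuple(table.loc[0, "subset"])
    final = None
    if refit_final:
        final = fit(
            data,
            replace(base_spec, covariates=chosen),
            sampler=final_sampler,
            mesh=mesh,
        )
    return SelectionReport(table=table, chosen=chosen, final_fit=final)


@dataclass
class CVResult:
    fold_of: np.ndarray  # fold index per observation
    per_fold: pd.DataFrame  # fold, n_obs, mean_error, coverage_pct
    mean_error: float  # pooled, prevalence units
    coverage_pct: float  # pooled % inside the 95% predictive BCI


def cross_validate(
    data: pd.DataFrame,
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    sampler: SamplerConfig | None = None,
    mesh: Mesh | None = None,
) -> CVResult:
    """k-fold cross-validation with spatial (kriging) held-out prediction.

    Each fold refits on the training clusters and predicts the held-out
    clusters through the latent field at their coordinates; held-out
    prediction adds fresh location-effect noise and binomial sampling so the
    95% interval is a genuine predictive interval for the observed
    prevalence.  Mean error is observed minus predicted-median prevalence.
    """
    n_obs = len(data)
    if n_obs < k:
        raise ValueError("fewer clusters than folds")
    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(k), int(np.ceil(n_obs / k)))[:n_obs]
    rng.shuffle(fold_of)
    if np.bincount(fold_of, minlength=k).min() == 0:
        raise ValueError("a fold received zero clusters")

    errors = []
    covered = []
    fold_rows = []
    base_sampler = sampler or SamplerConfig()
    for fold in range(k):
        test = data[fold_of == fold]
        train = data[fold_of != fold].reset_index(drop=True)
        fold_sampler = replace(base_sampler, seed=base_sampler.seed + fold)
        res = fit(train, spec, sampler=fold_sampler, mesh=mesh)
        pts = test[["x_km", "y_km"]].to_numpy()
        fold_errs = []
        fold_cov = []
        for year in np.unique(test["year"]):
            sel = test["year"] == year
            x_new = _design_for_new(res, test[sel])
            eta = posterior_linpred(
                res,
                pts[sel.to_numpy()],
                x_new,
                float(year),
                include_lambda_noise=True,
                rng=np.random.default_rng(seed + 100 + fold),
            )
            p_draws = expit(eta)  # (S, n_test)
            n_test = test.loc[sel, "n"].to_numpy()
            obs_prev = test.loc[sel, "y"].to_numpy() / n_test
            pred_median = np.median(p_draws, axis=0)
            y_rep = np.random.default_rng(seed + 200 + fold).binomial(
                n_test[None, :], p_draws
            )
            prev_rep = y_rep / n_test[None, :]
            lo = np.quantile(prev_rep, 0.025, axis=0)
            hi = np.quantile(prev_rep, 0.975, axis=0)
            fold_errs.extend(obs_prev - pred_median)
            fold_cov.extend((obs_prev >= lo) & (obs_prev <= hi))
        errors.extend(fold_errs)
        covered.extend(fold_cov)
        fold_rows.append(
            {
                "fold": fold,
                "n_obs": len(fold_errs),
                "mean_error": float(np.mean(fold_errs)),
                "coverage_pct": 100.0 * float(np.mean(fold_cov)),
            }
        )
    return CVResult(
        fold_of=fold_of,
        per_fold=pd.DataFrame(fold_rows),
        mean_error=float(np.mean(errors)),
        coverage_pct=100.0 * float(np.mean(covered)),
    )


def _design_for_new(result: PosteriorResult, new_data: pd.DataFrame) -> np.ndarray:
    """Design columns for new rows using the training scaling and cut points."""
    struct = result.structure
    spec = struct.spec
    cols = []
    for name in spec.covariates:
        raw = new_data[name].to_numpy(dtype=float)
        if spec.form_of(name) == "categorical3":
            q1, q2 = struct.tertile_cuts[name]
            codes = np.digitize(raw, [q1, q2])
            cols.append((codes == 1).astype(float))
            cols.append((codes == 2).astype(float))
        else:
            cols.append(struct.scalers[name].transform(raw))
    if not cols:
        return np.empty((len(new_data), 0))
    return np.column_stack(cols)
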