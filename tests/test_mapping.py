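import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from geoprev.inference import ModelSpec, SamplerConfig, fit, posterior_summary
from geoprev.mapping import (
    AdminAggregate,
    PixelPrediction,
    PredictionGrid,
    aggregate_admin,
    classify_trend,
    infected_counts,
    predict_grid,
    relative_change,
)
from geoprev.model import TemporalSpec


def _prediction(draws, points=None):
    draws = np.asarray(draws, dtype=float)
    n_pix = draws.shape[1]
    if points is None:
        points = np.column_stack([np.arange(n_pix, dtype=float), np.zeros(n_pix)])
    return PixelPrediction(
        year=2007.0,
        points=np.asarray(points, dtype=float),
        draws=draws,
        mask=np.ones(n_pix, dtype=bool),
        median=np.median(draws, axis=0),
        sd=np.std(draws, axis=0),
        lower=np.quantile(draws, 0.025, axis=0),
        upper=np.quantile(draws, 0.975, axis=0),
    )


UNIT_SQUARES = {
    "type": "FeatureCollection",
    "features": [
        {
            "type": "Feature",
            "id": "A",
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[-0.5, -1], [1.5, -1], [1.5, 1], [-0.5, 1], [-0.5, -1]]],
            },
            "properties": {},
        },
        {
            "type": "Feature",
            "id": "B",
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[1.5, -1], [3.5, -1], [3.5, 1], [1.5, 1], [1.5, -1]]],
            },
            "properties": {},
        },
    ],
}


class TestPredictGrid:
    def test_nofield_matches_intercept(self, nofield_data, nofield_spec):
        res = fit(
            nofield_data,
            nofield_spec,
            SamplerConfig(n_chains=1, n_warmup=100, n_keep=300, seed=1),
        )
        grid = PredictionGrid(
            points=np.array([[10.0, 10.0], [50.0, 50.0]]),
            covariates={},
            population=np.array([100.0, 200.0]),
        )
        pred = predict_grid(res, grid, 2007.0)
        med_b0, _, _ = posterior_summary(res, "beta0")
        np.testing.assert_allclose(pred.median, expit(med_b0), atol=1e-10)

    def test_monotone_in_positive_covariate(self, fitted_result):
        beta_med = np.median(fitted_result.draws["beta"], axis=0)
        pts = np.array([[60.0, 60.0]])
        pop = np.array([10.0])
        lo = predict_grid(
            fitted_result,
            PredictionGrid(points=pts, covariates={"cov1": [0.0], "cov2": [0.0]}, population=pop),
            2007.0,
        )
        hi = predict_grid(
            fitted_result,
            PredictionGrid(points=pts, covariates={"cov1": [1.0], "cov2": [0.0]}, population=pop),
            2007.0,
        )
        assert np.sign(hi.median[0] - lo.median[0]) == np.sign(beta_med[0])

    def test_missing_covariate_pixel_masked(self, fitted_result):
        grid = PredictionGrid(
            points=np.array([[40.0, 40.0], [60.0, 60.0]]),
            covariates={"cov1": [0.1, np.nan], "cov2": [0.0, 0.2]},
            population=np.array([1.0, 1.0]),
        )
        pred = predict_grid(fitted_result, grid, 2011.0)
        assert pred.mask.tolist() == [True, False]
        assert np.isnan(pred.median[1])
        assert np.isfinite(pred.median[0])

    def test_interval_contains_median(self, fitted_result):
        rng = np.random.default_rng(0)
        pts = rng.uniform(20, 100, (10, 2))
        grid = PredictionGrid(
            points=pts,
            covariates={"cov1": rng.normal(size=10), "cov2": rng.normal(size=10)},
            population=np.ones(10),
        )
        pred = predict_grid(fitted_result, grid, 2014.0)
        assert (pred.lower <= pred.median).all()
        assert (pred.median <= pred.upper).all()

    def test_shrinkage_toward_observed_at_huge_cluster(self):
        # a training cluster with enormous n pins the local predictive median
        rng = np.random.default_rng(9)
        n_c = 40
        df = pd.DataFrame(
            {
                "cluster_id": [f"c{i}" for i in range(n_c)],
                "year": 2007.0,
                "x_km": rng.uniform(0, 60, n_c),
                "y_km": rng.uniform(0, 60, n_c),
                "n": 30,
            }
        )
        df["y"] = rng.binomial(30, 0.15, n_c)
        df.loc[0, ["x_km", "y_km", "n"]] = [30.0, 30.0, 20000]
        df.loc[0, "y"] = int(20000 * 0.35)
        spec = ModelSpec(
            covariates=(),
            temporal=TemporalSpec(knots=(2007.0,), mode="exchangeable"),
            use_lambda=False,
        )
        res = fit(
            df, spec, SamplerConfig(n_chains=1, n_warmup=150, n_keep=300, seed=2)
        )
        grid = PredictionGrid(
            points=np.array([[30.0, 30.0]]), covariates={}, population=np.array([1.0])
        )
        pred = predict_grid(res, grid, 2007.0)
        assert pred.median[0] == pytest.approx(0.35, abs=0.05)


class TestInfectedCounts:
    def test_simple_product(self):
        pred = _prediction(np.full((200, 1), 0.134))
        out = infected_counts(pred, np.array([1000.0]))
        assert out["median"][0] == pytest.approx(134.0)

    def test_zero_population(self):
        pred = _prediction(np.random.default_rng(0).uniform(0, 1, (100, 2)))
        out = infected_counts(pred, np.array([0.0, 10.0]))
        assert out["median"][0] == 0.0
        assert (out["upper"][0] == 0.0) and (out["upper"][1] > 0.0)

    def test_negative_population_raises(self):
        pred = _prediction(np.full((10, 1), 0.1))
        with pytest.raises(ValueError):
            infected_counts(pred, np.array([-5.0]))

    def test_quantile_non_additivity_documented(self):
        # sum of pixel medians differs from median of summed draws in general
        rng = np.random.default_rng(1)
        draws = rng.lognormal(mean=-2.0, sigma=1.0, size=(500, 3)).clip(0, 1)
        pred = _prediction(draws)
        pop = np.array([100.0, 200.0, 50.0])
        out = infected_counts(pred, pop)
        sum_of_medians = out["median"].sum()
        median_of_sums = np.median((draws * pop).sum(axis=1))
        assert sum_of_medians != pytest.approx(median_of_sums, rel=1e-6)


class TestAggregateAdmin:
    def test_uniform_prevalence_exact(self):
        draws = np.full((300, 4), 0.21)
        pred = _prediction(draws, points=[[0, 0], [1, 0], [2, 0], [3, 0]])
        aggs = aggregate_admin(pred, np.array([5.0, 10.0, 2.0, 8.0]), UNIT_SQUARES)
        for a in aggs:
            assert a.prevalence[0] == pytest.approx(0.21, abs=1e-12)

    def test_two_pixel_weighted_mean(self):
        draws = np.tile(np.array([0.1, 0.3]), (200, 1))
        pred = _prediction(draws, points=[[0, 0], [1, 0]])
        one_unit = {
            "type": "FeatureCollection",
            "features": [UNIT_SQUARES["features"][0]],
        }
        aggs = aggregate_admin(pred, np.array([100.0, 300.0]), one_unit)
        assert aggs[0].prevalence[0] == pytest.approx(0.25, abs=1e-12)

    def test_whole_domain_identity(self):
        rng = np.random.default_rng(2)
        draws = rng.uniform(0, 1, size=(150, 4))
        pop = np.array([10.0, 20.0, 5.0, 40.0])
        pred = _prediction(draws, points=[[0, 0], [1, 0], [2, 0], [3, 0]])
        whole = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "id": "all",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[-1, -1], [4, -1], [4, 1], [-1, 1], [-1, -1]]],
                    },
                    "properties": {},
                }
            ],
        }
        aggs = aggregate_admin(pred, pop, whole)
        per_draw = (draws * pop).sum(axis=1) / pop.sum()
        med, lo, hi = np.percentile(per_draw, [50.0, 2.5, 97.5])
        assert aggs[0].prevalence == pytest.approx((med, lo, hi), rel=1e-12)

    def test_one_unit_partition_matches_whole_domain(self):
        rng = np.random.default_rng(3)
        draws = rng.uniform(0, 1, size=(100, 4))
        pop = np.array([1.0, 2.0, 3.0, 4.0])
        pred = _prediction(draws, points=[[0, 0], [1, 0], [2, 0], [3, 0]])
        split = aggregate_admin(pred, pop, UNIT_SQUARES)
        total_count_draws = (draws * pop).sum(axis=1)
        got = sum(
            np.array((draws[:, :2] * pop[:2]).sum(axis=1))
            + np.array((draws[:, 2:] * pop[2:]).sum(axis=1))
        )
        # counts add across a partition, draw by draw
        a_draws = (draws[:, :2] * pop[:2]).sum(axis=1)
        b_draws = (draws[:, 2:] * pop[2:]).sum(axis=1)
        np.testing.assert_allclose(
            np.median(a_draws + b_draws), np.median(total_count_draws), rtol=1e-12
        )
        assert {a.unit_id for a in split} == {"A", "B"}

    def test_zero_population_unit_flagged(self):
        draws = np.full((200, 2), 0.4)
        pred = _prediction(draws, points=[[0, 0], [2, 0]])
        aggs = aggregate_admin(pred, np.array([10.0, 0.0]), UNIT_SQUARES)
        b = next(a for a in aggs if a.unit_id == "B")
        assert np.isnan(b.prevalence[0])


class TestRelativeChange:
    def test_no_change(self):
        out = relative_change([0.2, 0.3], [0.2, 0.3])
        np.testing.assert_allclose(out, 0.0)

    def test_paper_magnitude_180pct_increase(self):
        # 0.10 -> 0.28 gives (0.10-0.28)/0.10 = -1.8, i.e. a 180% increase
        out = relative_change([0.10], [0.28])
        assert out[0] == pytest.approx(-1.8)

    def test_full_decrease(self):
        assert relative_change([0.15], [0.0])[0] == pytest.approx(1.0)

    def test_zero_baseline_masked(self):
        assert np.isnan(relative_change([0.0], [0.2])[0])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            relative_change([0.1, 0.2], [0.1])


class TestClassifyTrend:
    def test_decreasing(self):
        assert classify_trend((0.10, 0.08, 0.12), (0.15, 0.12, 0.18)) == "decreasing"

    def test_increasing(self):
        assert classify_trend((0.20, 0.18, 0.22), (0.15, 0.12, 0.18)) == "increasing"

    def test_stable(self):
        assert classify_trend((0.15, 0.13, 0.17), (0.15, 0.12, 0.18)) == "stable"

    def test_antisymmetric_for_separated_summaries(self):
        a = (0.10, 0.08, 0.12)
        b = (0.20, 0.18, 0.22)
        assert classify_trend(a, b) == "decreasing"
        assert classify_trend(b, a) == "increasing"
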