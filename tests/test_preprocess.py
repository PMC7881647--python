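import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from shapely.geometry import LineString, Point, Polygon

from geoprev.preprocess import (
    aggregate_to_clusters,
    annual_mean,
    categorize_tertiles,
    distance_to_water,
    extract_at_points,
    prune_collinear,
    sar_smoothness,
    standardize,
)
from geoprev.raster import Raster


def _individuals(n=30, positives=4, cluster="a", year=2007):
    return pd.DataFrame(
        {
            "cluster_id": cluster,
            "year": year,
            "x_km": 1.0,
            "y_km": 2.0,
            "positive": [1] * positives + [0] * (n - positives),
        }
    )


class TestAggregate:
    def test_counts(self):
        out = aggregate_to_clusters(_individuals(30, 4))
        assert out.loc[0, "n"] == 30
        assert out.loc[0, "y"] == 4

    def test_all_positive_boundary(self):
        out = aggregate_to_clusters(_individuals(12, 12))
        assert out.loc[0, "y"] == out.loc[0, "n"] == 12

    def test_cluster_without_coordinates_dropped(self):
        good = _individuals(30, 4, cluster="a")
        bad = _individuals(33, 5, cluster="b")
        bad["x_km"] = np.nan
        out = aggregate_to_clusters(pd.concat([good, bad], ignore_index=True))
        assert list(out["cluster_id"]) == ["a"]

    def test_covariate_means_and_proportions(self):
        df = _individuals(4, 1)
        df["age"] = [20.0, 30.0, 40.0, 50.0]
        df["edu"] = [1, 0, 1, 1]
        out = aggregate_to_clusters(df, covariates=["age", "edu"])
        assert out.loc[0, "age"] == 35.0
        assert out.loc[0, "edu"] == 0.75

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            out = aggregate_to_clusters(_individuals(0, 0).iloc[0:0])
        assert out.empty


class TestStandardize:
    def test_simple_example(self):
        z, scaler = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert scaler.mean == 2.0 and scaler.sd == 1.0

    def test_constant_raises(self):
        with pytest.raises(ValueError, match="wealth"):
            standardize([5.0, 5.0, 5.0], name="wealth")

    def test_roundtrip(self):
        x = np.random.default_rng(0).normal(10, 3, size=50)
        z, scaler = standardize(x)
        np.testing.assert_allclose(scaler.inverse(z), x, rtol=1e-12)

    def test_idempotent_on_standardized(self):
        x = np.random.default_rng(1).normal(size=80)
        z, _ = standardize(x)
        z2, _ = standardize(z)
        np.testing.assert_allclose(z2, z, atol=1e-10)


class TestPruneCollinear:
    def test_paper_education_pair(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=400)
        women = base + 0.27 * rng.normal(size=400)
        husbands = base + 0.27 * rng.normal(size=400)
        table = pd.DataFrame({"edu_women": women, "edu_husbands": husbands})
        r = table.corr().iloc[0, 1]
        assert r > 0.8
        retained, report = prune_collinear(
            table, priority=["edu_women", "edu_husbands"]
        )
        assert retained == ["edu_women"]
        assert report.loc[0, "dropped"] == "edu_husbands"

    def test_nothing_to_drop(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        retained, report = prune_collinear(table, priority=list("abc"))
        assert retained == list("abc")
        assert report.empty

    def test_three_mutually_correlated_keeps_one(self):
        # brute-force expectation: greedy in priority order leaves only 'a'
        rng = np.random.default_rng(4)
        base = rng.normal(size=500)
        table = pd.DataFrame(
            {k: base + 0.1 * rng.normal(size=500) for k in ("b", "a", "c")}
        )
        corr = table.corr().abs().to_numpy()
        assert (corr[np.triu_indices(3, 1)] > 0.8).all()
        retained, _ = prune_collinear(table, priority=["a", "b", "c"])
        assert retained == ["a"]

    def test_no_retained_pair_exceeds_threshold(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=300)
        table = pd.DataFrame(
            {
                "a": base,
                "b": base + 0.2 * rng.normal(size=300),
                "c": rng.normal(size=300),
                "d": base + 2.0 * rng.normal(size=300),
            }
        )
        retained, _ = prune_collinear(table, priority=list("abcd"))
        sub = table[retained].corr().abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.8

    def test_missing_priority_raises(self):
        base = np.linspace(0, 1, 50)
        table = pd.DataFrame({"a": base, "b": base * 2 + 1e-6})
        with pytest.raises(ValueError, match="priority"):
            prune_collinear(table, priority=["a"])


class TestExtractAtPoints:
    @pytest.fixture
    def raster(self):
        return Raster(data=np.arange(16.0).reshape(4, 4), xll=0, yll=0, cellsize=1.0)

    def test_at_pixel_center(self, raster):
        # center of row 0, col 2 is (2.5, 3.5)
        assert extract_at_points(raster, [[2.5, 3.5]])[0] == 2.0

    def test_boundary_tie_break_deterministic(self, raster):
        # point exactly between two pixel centers -> lower (row, col) index
        v1 = extract_at_points(raster, [[2.0, 3.5]])[0]
        v2 = extract_at_points(raster, [[2.0, 3.5]])[0]
        assert v1 == v2 == 1.0  # col 1 (the lower index) wins

    def test_constant_raster_displacement_free(self, raster):
        const = Raster(data=np.full((4, 4), 7.0), xll=0, yll=0, cellsize=1.0)
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 4, (20, 2))
        assert (extract_at_points(const, pts) == 7.0).all()

    def test_nodata_flagged(self, raster):
        raster.data[0, 0] = raster.nodata
        assert np.isnan(extract_at_points(raster, [[0.5, 3.5]])[0])


class TestDistanceToWater:
    def test_inside_polygon_zero(self):
        poly = Polygon([(0, 0), (4, 0), (4, 4), (0, 4)])
        assert distance_to_water([[2.0, 2.0]], [poly])[0] == 0.0

    def test_distance_to_segment(self):
        seg = LineString([(0, 0), (10, 0)])
        assert distance_to_water([[5.0, 5.0]], [seg])[0] == pytest.approx(5.0)

    def test_multiple_features_equals_bruteforce(self):
        rng = np.random.default_rng(7)
        geoms = [Point(xy) for xy in rng.uniform(0, 10, (8, 2))]
        pts = rng.uniform(0, 10, (15, 2))
        got = distance_to_water(pts, geoms)
        brute = np.array(
            [min(np.hypot(p[0] - g.x, p[1] - g.y) for g in geoms) for p in pts]
        )
        np.testing.assert_allclose(got, brute, rtol=1e-12)

    def test_geojson_mapping_accepted(self):
        gj = {"type": "Point", "coordinates": [0.0, 0.0]}
        assert distance_to_water([[3.0, 4.0]], [gj])[0] == pytest.approx(5.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            distance_to_water([[0.0, 0.0]], [])


class TestAnnualMean:
    def test_identical_months(self):
        idx = pd.date_range("2011-01-01", periods=12, freq="MS")
        s = pd.Series(3.7, index=idx)
        assert annual_mean(s, 2011) == pytest.approx(3.7, rel=1e-12)

    def test_two_values(self):
        s = pd.Series([10.0, 20.0], index=pd.to_datetime(["2007-02-01", "2007-08-01"]))
        assert annual_mean(s, 2007) == 15.0

    def test_missing_month_excluded(self):
        idx = pd.date_range("2014-01-01", periods=12, freq="MS")
        vals = np.full(12, 2.0)
        vals[5] = np.nan
        assert annual_mean(pd.Series(vals, index=idx), 2014) == 2.0

    def test_empty_year_flagged(self):
        s = pd.Series([1.0], index=pd.to_datetime(["2007-01-01"]))
        with pytest.warns(UserWarning):
            assert np.isnan(annual_mean(s, 2008))


def _dense_sar_oracle(data: np.ndarray) -> float:
    """Independent dense ML fit of the SAR lag model for the oracle check."""
    nr, nc = data.shape
    n = nr * nc
    w = np.zeros((n, n))
    for r in range(nr):
        for c in range(nc):
            i = r * nc + c
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc:
                    w[i, rr * nc + cc] = 1.0
    w = w / w.sum(axis=1, keepdims=True)
    y = data.ravel()
    y = (y - y.mean()) / y.std()
    eig = np.linalg.eigvals(w).real

    def nll(rho):
        e = y - rho * (w @ y)
        e = e - e.mean()
        return 0.5 * n * np.log(e @ e / n) - np.sum(np.log(np.abs(1 - rho * eig)))

    res = minimize_scalar(nll, bounds=(1.0 / eig.min() + 1e-6, 1 - 1e-6), method="bounded")
    return float(res.x)


class TestSarSmoothness:
    def test_white_noise_near_zero(self):
        # Monte-Carlo over 20 seeds: mean coefficient must hug zero
        coefs = [
            sar_smoothness(np.random.default_rng(s).standard_normal((15, 15)))
            for s in range(20)
        ]
        assert abs(np.mean(coefs)) < 0.1

    def test_smooth_surface_above_point_nine(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(1)
        smooth = gaussian_filter(rng.standard_normal((30, 30)), sigma=4.0)
        assert sar_smoothness(smooth) > 0.9

    def test_checkerboard_negative_and_matches_oracle(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        board = board + 0.01 * np.random.default_rng(2).standard_normal((8, 8))
        got = sar_smoothness(board)
        assert got < 0.0
        assert got == pytest.approx(_dense_sar_oracle(board), abs=1e-4)

    def test_random_surface_matches_oracle(self):
        data = np.random.default_rng(3).standard_normal((7, 9))
        assert sar_smoothness(data) == pytest.approx(_dense_sar_oracle(data), abs=1e-4)

    def test_affine_invariance(self):
        data = np.random.default_rng(4).standard_normal((10, 10))
        a = sar_smoothness(data)
        b = sar_smoothness(3.5 * data - 11.0)
        assert a == pytest.approx(b, abs=1e-6)

    def test_constant_surface_raises(self):
        with pytest.raises(ValueError):
            sar_smoothness(np.ones((5, 5)))

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            sar_smoothness(np.random.default_rng(0).standard_normal((2, 5)))


class TestCategorizeTertiles:
    def test_three_levels(self):
        codes = categorize_tertiles(np.arange(30.0))
        assert set(codes) == {0, 1, 2}
        assert np.bincount(codes).tolist() == [10, 10, 10]

    def test_tie_raises(self):
        with pytest.raises(ValueError):
            categorize_tertiles(np.zeros(10), name="flat")
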