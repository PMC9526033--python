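"""Suitability curves, HSI combination, model selection, habitat
classification, decadal ANOVA and the SST trend."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stockhab as sh
from stockhab.errors import ValidationError
from stockhab.habitat import (
    aicc,
    classify_and_area,
    combine_hsi,
    decadal_anova,
    fit_si_fitting_based,
    fit_si_regression_based,
    standardize_abundance,
    validate_and_select,
    winter_mean,
    winter_sst_trend,
)


class TestStandardize:
    def test_scaling(self):
        np.testing.assert_allclose(standardize_abundance([2, 5, 10]), [0.2, 0.5, 1.0])

    def test_single_record(self):
        np.testing.assert_allclose(standardize_abundance([7.0]), [1.0])

    def test_tied_maximum(self):
        np.testing.assert_allclose(standardize_abundance([10, 4, 10]), [1.0, 0.4, 1.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            standardize_abundance([0.0, 0.0])


class TestFittingBasedSI:
    def test_recovers_gaussian_generating_curve(self):
        # SI = 0.8 at 18.2 and 20.5 fixes sigma; exact observations on the
        # curve must give back mu within 0.05 and the range ends within 0.1
        sigma = 1.15 / np.sqrt(2 * np.log(1 / 0.8))
        rng = np.random.default_rng(0)
        x = rng.uniform(15.0, 24.0, 400)
        y = np.exp(-((x - 19.35) ** 2) / (2 * sigma**2))
        curve = fit_si_fitting_based(x, y, "sst")
        assert curve.params["mu"] == pytest.approx(19.35, abs=0.05)
        assert curve.optimal_range[0] == pytest.approx(18.2, abs=0.1)
        assert curve.optimal_range[1] == pytest.approx(20.5, abs=0.1)
        assert curve.evaluate(curve.params["mu"]) == pytest.approx(1.0)

    def test_degenerate_observations_rejected(self):
        x = np.linspace(0, 1, 50)
        with pytest.raises(ValidationError):
            fit_si_fitting_based(x, np.ones_like(x))
        with pytest.raises(ValidationError):
            fit_si_fitting_based([1.0, 1.0, 1.0, 1.0, 1.0], [0.1, 0.5, 1.0, 0.5, 0.2])


class TestRegressionBasedSI:
    def test_quadratic_peak_recovered_exactly(self):
        x = np.linspace(0.0, 10.0, 40)
        y = -0.04 * (x - 5.0) ** 2 + 1.0
        curve = fit_si_regression_based(x, y, degree=2)
        a2 = curve.params["coeffs"][0]
        assert a2 == pytest.approx(-0.04, rel=1e-9)
        assert curve.params["p_value"] < 1e-10

    def test_degree_one_reduces_to_simple_ols(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        x = np.linspace(0.0, 1.0, 30)
        y = 0.3 * x + 0.2 + rng.normal(0, 0.02, 30)
        curve = fit_si_regression_based(x, y, degree=1)
        assert curve.params["coeffs"][0] == pytest.approx(
            stats.linregress(x, y).slope, rel=1e-9
        )

    def test_predictions_clipped_to_unit_interval(self):
        x = np.linspace(0.0, 10.0, 40)
        y = -0.1 * (x - 5.0) ** 2 + 1.0  # goes well below 0 at the edges
        curve = fit_si_regression_based(x, y, degree=2)
        vals = curve.evaluate(np.linspace(-5, 15, 200))
        assert vals.min() == 0.0 and vals.max() <= 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_si_regression_based([1, 2, 3], [0.1, 0.9, 0.2], degree=3)


class TestCombiners:
    def test_arithmetic_mean(self):
        assert combine_hsi("am", np.array([[0.4], [0.8]]))[0] == pytest.approx(0.6)

    def test_geometric_mean(self):
        assert combine_hsi("gm", np.array([[0.25], [1.0]]))[0] == pytest.approx(0.5)

    def test_gm_zero_annihilates(self):
        assert combine_hsi("gm", np.array([[0.0], [0.9], [0.8]]))[0] == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=5))
    def test_gm_never_exceeds_am(self, sis):
        stack = np.asarray(sis)[:, None]
        assert combine_hsi("gm", stack)[0] <= combine_hsi("am", stack)[0] + 1e-12


def test_aicc_direct_formula():
    assert aicc(24.0, 24, 3) == pytest.approx(7.2)
    # decreasing RSS at fixed n, k decreases AICc
    assert aicc(10.0, 24, 3) < aicc(24.0, 24, 3)
    with pytest.raises(ValidationError):
        aicc(1.0, 4, 3)


class TestModelSelection:
    def test_zero_noise_recovery(self, small_noiseless_grid):
        """The generating model (fitting-based AM over depth+SST) must be
        selected with a perfect validation fit and exact SI parameters."""
        res = validate_and_select(small_noiseless_grid, range(1971, 1981), [1981, 1982])
        assert res.best_form == "fitting_based"
        assert res.best_model.combiner == "am"
        assert res.best_model.variables == ("depth", "sst")
        assert res.validation.r2 == pytest.approx(1.0, abs=1e-9)
        truth = sh.synthetic.DEFAULT_SI_TRUE
        for var in ("depth", "sst"):
            mu, sigma = truth[var]
            assert res.best_model.si_curves[var].params["mu"] == pytest.approx(mu, rel=0.01)
            assert res.best_model.si_curves[var].params["sigma"] == pytest.approx(sigma, rel=0.01)

    def test_candidate_table_complete(self, small_noiseless_grid):
        res = validate_and_select(small_noiseless_grid, range(1971, 1981), [1981, 1982])
        assert len(res.table) == 7 * 2 * 2
        assert res.table["r2"].iloc[0] == res.table["r2"].max()

    def test_empty_periods_rejected(self, small_noiseless_grid):
        with pytest.raises(ValidationError):
            validate_and_select(small_noiseless_grid, [], [1981])

    def test_results_object_predicts_in_unit_interval(self, small_noiseless_grid):
        res = sh.HabitatSuitabilityModel(
            small_noiseless_grid, range(1971, 1981), [1981, 1982]).fit()
        df = res.predict_year(1975)
        assert df["hsi"].between(0, 1).all()
        assert "best model" in res.summary()


class TestWinterMean:
    def test_constant_field(self, small_noiseless_grid):
        wm = winter_mean(small_noiseless_grid, 1971)
        assert set(wm.data_vars) == {"sst_c", "sss", "depth_m"}

    def test_three_month_average(self):
        import xarray as xr

        months = np.array([12, 1, 2])
        years = np.arange(1971, 1973)
        sst = np.full((2, 3, 1, 1), np.nan)
        sst[0, 0] = 18.0   # Dec 1971
        sst[1, 1] = 19.0   # Jan 1972
        sst[1, 2] = 20.0   # Feb 1972
        ds = xr.Dataset(
            {
                "depth_m": (("lat", "lon"), [[50.0]]),
                "sst_c": (("year", "month", "lat", "lon"), sst),
                "sss": (("year", "month", "lat", "lon"), np.where(np.isnan(sst), np.nan, 34.0)),
            },
            coords={"lat": [25.0], "lon": [121.0], "year": years, "month": months},
        )
        grid = sh.EnvironmentalGrid(ds)
        assert float(winter_mean(grid, 1971)["sst_c"].mean()) == pytest.approx(19.0)

    def test_missing_month_named_in_error(self):
        import xarray as xr

        months = np.array([12, 1, 2])
        years = np.arange(1971, 1973)
        sst = np.full((2, 3, 1, 1), np.nan)
        sst[0, 0] = 18.0
        sst[1, 1] = 19.0  # Feb missing
        ds = xr.Dataset(
            {
                "depth_m": (("lat", "lon"), [[50.0]]),
                "sst_c": (("year", "month", "lat", "lon"), sst),
                "sss": (("year", "month", "lat", "lon"), sst),
            },
            coords={"lat": [25.0], "lon": [121.0], "year": years, "month": months},
        )
        with pytest.raises(ValidationError, match="month 2"):
            winter_mean(sh.EnvironmentalGrid(ds), 1971)


class TestClassification:
    def test_equal_area_three_classes(self):
        out = classify_and_area([0.75, 0.5, 0.2], [25.0, 25.0, 25.0])
        assert out["pct_optimal"] == pytest.approx(100 / 3)
        assert out["pct_average"] == pytest.approx(100 / 3)
        assert out["pct_poor"] == pytest.approx(100 / 3)

    def test_all_optimal(self):
        out = classify_and_area([0.8, 0.9], [25.0, 26.0])
        assert out["pct_optimal"] == pytest.approx(100.0)

    def test_boundary_values_use_closed_upper_rule(self):
        out = classify_and_area([0.7, 0.3], [25.0, 25.0])
        assert out["pct_optimal"] == pytest.approx(50.0)
        assert out["pct_average"] == pytest.approx(50.0)

    def test_percentages_always_sum_to_100(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            hsi = rng.random(rng.integers(1, 60))
            lat = rng.uniform(20, 40, hsi.size)
            out = classify_and_area(hsi, lat)
            assert out["pct_optimal"] + out["pct_average"] + out["pct_poor"] == pytest.approx(
                100.0, abs=1e-9
            )

    def test_cosine_latitude_weighting(self):
        # one optimal cell at high latitude counts less than a poor cell at low
        out = classify_and_area([0.9, 0.1], [60.0, 0.0])
        assert out["pct_optimal"] < 50.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            classify_and_area([np.nan], [25.0])


class TestDecadalAnova:
    def test_identical_groups_f_zero(self):
        res = decadal_anova({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert res.f_stat == pytest.approx(0.0)

    def test_textbook_three_group_example(self):
        groups = {"g1": [6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
                  "g2": [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
                  "g3": [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]}
        res = decadal_anova(groups)
        # hand-computed between/within mean squares
        data = [np.asarray(v) for v in groups.values()]
        grand = np.concatenate(data).mean()
        ssb = sum(d.size * (d.mean() - grand) ** 2 for d in data)
        ssw = sum(((d - d.mean()) ** 2).sum() for d in data)
        f_hand = (ssb / 2) / (ssw / 15)
        assert res.f_stat == pytest.approx(f_hand, rel=1e-12)

    def test_scheffe_is_conservative(self):
        from scipy import stats as sps

        rng = np.random.default_rng(4)
        groups = {k: rng.normal(i, 1.0, 8) for i, k in enumerate("abc")}
        res = decadal_anova(groups)
        data = [np.asarray(v) for v in groups.values()]
        n_total = sum(d.size for d in data)
        msw = sum(((d - d.mean()) ** 2).sum() for d in data) / (n_total - 3)
        for _, row in res.scheffe.iterrows():
            a = groups[row["group_a"]]
            b = groups[row["group_b"]]
            t = abs(a.mean() - b.mean()) / np.sqrt(msw * (1 / a.size + 1 / b.size))
            p_unadj = 2 * sps.t.sf(t, n_total - 3)
            assert row["p_scheffe"] >= p_unadj - 1e-12

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            decadal_anova({"a": [1.0], "b": [1.0, 2.0]})


class TestTrend:
    def test_exact_line_recovered_to_machine_precision(self):
        years = np.arange(1971, 2020)
        res = winter_sst_trend(years, 19.0 - 0.028 * (years - 1971))
        assert res.slope == pytest.approx(-0.028, abs=1e-12)
        assert res.r2 == pytest.approx(1.0)

    def test_constant_series_flagged(self):
        res = winter_sst_trend(np.arange(10), np.full(10, 19.0))
        assert res.slope == 0.0 and res.constant

    def test_noisy_series_within_three_se(self):
        rng = np.random.default_rng(6)
        years = np.arange(49)
        sst = 19.0 - 0.028 * years + rng.normal(0, 0.15, 49)
        from scipy import stats as sps

        res = winter_sst_trend(years, sst)
        se = sps.linregress(years, sst).stderr
        assert abs(res.slope - (-0.028)) < 3 * se
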