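"""Weather windows, shape ~ climate models, AIC comparison, region tests."""

import numpy as np
import pandas as pd
import pytest

import leafmorph as lm
from leafmorph.climate import (
    _fit_one,
    _window_bounds,
    aggregate_stations,
    compare_aic,
    convert_units,
    cramers_v,
    fit_models,
    region_tests,
    summarize_window,
    summarize_windows,
    trend,
)
from leafmorph.errors import ComparabilityError, CoverageError, ParameterError


def daily_series(start="2000-01-01", end="2001-06-30", tavg=20.0):
    dates = pd.date_range(start, end, freq="D")
    return pd.DataFrame(
        {
            "site": "s1",
            "date": dates,
            "TAVG": float(tavg),
            "TMAX": float(tavg) + 5,
            "TMIN": float(tavg) - 5,
            "PRCP": 0.1,
        }
    )


class TestAggregateStations:
    def test_single_station_identity(self):
        s = daily_series().assign(station="a").drop(columns="site")
        out = aggregate_stations(s, site="city")
        assert np.allclose(out["TAVG"], 20.0)
        assert (out["site"] == "city").all()

    def test_two_stations_average(self):
        a = daily_series(tavg=10.0).assign(station="a")
        b = daily_series(tavg=20.0).assign(station="b")
        out = aggregate_stations(pd.concat([a, b]), site="city")
        assert np.allclose(out["TAVG"], 15.0)

    def test_missing_from_one_station_uses_other(self):
        a = daily_series(tavg=10.0).assign(station="a")
        b = daily_series(tavg=20.0).assign(station="b")
        a.loc[0, "TAVG"] = np.nan
        out = aggregate_stations(pd.concat([a, b]), site="city")
        assert out["TAVG"].iloc[0] == 20.0

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_stations(pd.DataFrame(), site="city")

    def test_pseudo_station_split_recovery(self, rng):
        """Averaging 5 noisy station copies recovers the site series."""
        base = daily_series()
        sigma = 2.0
        stations = []
        for k in range(5):
            s = base.copy().assign(station=f"st{k}")
            s["TAVG"] = s["TAVG"] + rng.normal(0, sigma, len(s))
            stations.append(s)
        out = aggregate_stations(pd.concat(stations), site="city")
        rmse = np.sqrt(np.mean((out["TAVG"] - base["TAVG"]) ** 2))
        assert rmse < 1.8 * sigma / np.sqrt(5)


class TestConvertUnits:
    def test_temperature_tenths_of_degree(self):
        raw = pd.DataFrame({"TAVG": [215, -40], "PRCP": [0, 10]})
        out = convert_units(raw)
        assert out["TAVG"].tolist() == [21.5, -4.0]

    def test_precip_tenths_of_inch(self):
        raw = pd.DataFrame({"PRCP": [0, 10, 3]})
        out = convert_units(raw)
        assert out["PRCP"].tolist() == [0.0, 1.0, 0.3]
        assert np.log1p(out["PRCP"].iloc[0]) == 0.0


class TestWindows:
    def test_gs_window_six_calendar_months(self):
        start, end = _window_bounds(pd.Timestamp("2000-07-01"), "GS")
        assert start == pd.Timestamp("2000-01-01")
        assert end == pd.Timestamp("2000-07-01")

    def test_yl_window_365_days(self):
        start, _ = _window_bounds(pd.Timestamp("2000-12-31"), "YL")
        assert (pd.Timestamp("2000-12-31") - start).days == 365

    def test_month_end_clamping(self):
        start, _ = _window_bounds(pd.Timestamp("2000-08-31"), "GS")
        assert start == pd.Timestamp("2000-02-29")  # clamped leap February

    def test_yl_hottest_coldest_formula(self):
        """Hottest month 30, coldest 10, rest 20 -> YL mean temperature 20."""
        s = daily_series()
        dates = pd.to_datetime(s["date"])
        s.loc[(dates.dt.year == 2000) & (dates.dt.month == 7), "TAVG"] = 30.0
        s.loc[(dates.dt.year == 2000) & (dates.dt.month == 1), "TAVG"] = 10.0
        ws = summarize_window(s, "2000-12-31", "YL")
        assert ws.AT == pytest.approx(20.0)

    def test_gs_mean_inclusive_of_collection_date(self):
        s = daily_series()
        s.loc[pd.to_datetime(s["date"]) == "2000-07-01", "TAVG"] = 120.0
        ws = summarize_window(s, "2000-07-01", "GS")
        n_days = (pd.Timestamp("2000-07-01") - pd.Timestamp("2000-01-01")).days + 1
        assert ws.AT == pytest.approx((20.0 * (n_days - 1) + 120.0) / n_days)
        assert ws.coverage == 1.0

    def test_doc_single_day(self):
        s = daily_series()
        ws = summarize_window(s, "2000-06-15", "DOC")
        assert ws.AT == 20.0
        assert ws.MAX == 25.0 and ws.MIN == 15.0
        assert ws.AP == pytest.approx(np.log1p(0.1))

    def test_doc_missing_day_null_with_zero_coverage(self):
        s = daily_series()
        s.loc[pd.to_datetime(s["date"]) == "2000-06-15", ["TAVG", "TMAX", "TMIN", "PRCP"]] = np.nan
        with pytest.warns(UserWarning, match="coverage"):
            ws = summarize_window(s, "2000-06-15", "DOC")
        assert ws.coverage == 0.0
        assert np.isnan(ws.AT)

    def test_collection_outside_series_raises(self):
        with pytest.raises(CoverageError):
            summarize_window(daily_series(), "2005-01-01", "GS", specimen_id="x")

    def test_row_order_invariance(self, rng):
        s = daily_series()
        shuffled = s.sample(frac=1.0, random_state=1).reset_index(drop=True)
        for model in ("GS", "YL", "DOC"):
            a = summarize_window(s, "2000-10-01", model)
            b = summarize_window(shuffled, "2000-10-01", model)
            assert a.AT == pytest.approx(b.AT)
            assert a.AP == pytest.approx(b.AP)

    def test_summarize_windows_wide_table(self):
        spec = lm.generate_specimens(3, seed=0)
        weather = lm.generate_weather(spec, seed=1)
        wide = summarize_windows(weather, spec)
        for col in ("AT_GS", "MAX_YL", "MIN_DOC", "AP_GS", "coverage_YL"):
            assert col in wide.columns
        assert len(wide) == 3
        assert wide[["AT_GS", "AT_YL"]].notna().all().all()


@pytest.fixture(scope="module")
def fitted_battery():
    """A linked synthetic dataset and its fitted model battery."""
    spec = lm.generate_specimens(80, seed=11, date_range=("1991-01-01", "1992-06-30"),
                                 regions=["South", "Southeast", "Northeast", "Upper Midwest"])
    weather = lm.generate_weather(spec, seed=12)
    wide = summarize_windows(weather, spec)
    rng = np.random.default_rng(13)
    desc = pd.DataFrame(
        {
            "id": spec["id"],
            "circularity": 0.5
            + 0.02 * wide.set_index("id").loc[spec["id"], "AT_GS"].values
            + rng.normal(0, 0.05, len(spec)),
            "aspect_ratio": rng.normal(3, 0.5, len(spec)),
        }
    )
    regions = spec.set_index("id")["climate_region"]
    fits = fit_models(desc, wide, regions=regions)
    return spec, wide, desc, regions, fits


class TestFitModels:
    def test_battery_shape(self, fitted_battery):
        *_, fits = fitted_battery
        names = [(f.response, f.name) for f in fits]
        assert len(fits) == 18  # 9 per descriptor
        for resp in ("circularity", "aspect_ratio"):
            for name in ("GS", "YL", "DOC", "INGS", "INYL", "INDOC",
                         "GS_noregion", "YL_noregion", "DOC_noregion"):
                assert (resp, name) in names

    def test_planted_slope_recovered(self, fitted_battery):
        _, _, _, _, fits = fitted_battery
        gs = next(f for f in fits if f.response == "circularity" and f.name == "GS_noregion")
        coef = gs.params["AT_GS"]
        lo, hi = gs.conf_int().loc["AT_GS"]
        assert coef > 0
        assert lo < 0.02 < hi

    def test_aic_matches_gaussian_closed_form(self, fitted_battery):
        """Oracle: AIC = 2k - 2*llf with the closed-form Gaussian logLik."""
        *_, fits = fitted_battery
        for f in fits:
            res = f.sm_result
            rss = float(np.sum(res.resid**2))
            n = f.n
            llf = -n / 2.0 * (np.log(2 * np.pi * rss / n) + 1.0)
            k = len(f.params) + 1
            assert f.llf == pytest.approx(llf, abs=1e-8)
            assert f.aic == pytest.approx(2 * k - 2 * llf, abs=1e-8)

    def test_three_collinear_points_perfect_fit(self):
        data = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [10.0, 20.0, 30.0]})
        f = _fit_one("line", "y ~ x", data, "y")
        assert f.rsquared == pytest.approx(1.0)
        assert np.allclose(f.sm_result.resid, 0.0, atol=1e-12)

    def test_rank_deficiency_detected(self):
        data = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "x": [1.0, 2.0, 3.0, 4.0]})
        data["x2"] = 2 * data["x"]
        with pytest.raises(ParameterError, match="rank deficient"):
            _fit_one("dup", "y ~ x + x2", data, "y")

    def test_single_region_rejected(self, fitted_battery):
        spec, wide, desc, regions, _ = fitted_battery
        one = regions.copy()
        one[:] = "South"
        with pytest.raises(ParameterError):
            fit_models(desc, wide, regions=one)

    def test_null_slope_type_one_error_rate(self, fitted_battery):
        """Pure-noise responses: ~5% of AT_GS slopes significant at 0.05."""
        spec, wide, desc, regions, _ = fitted_battery
        data = desc.merge(wide, on="id").merge(
            regions.rename("region").reset_index().rename(columns={"index": "id"}), on="id"
        )
        rng = np.random.default_rng(99)
        hits = 0
        n_sims = 100
        for _ in range(n_sims):
            data["noise"] = rng.normal(size=len(data))
            f = _fit_one("GS", "noise ~ AT_GS + MAX_GS + MIN_GS + AP_GS + C(region)",
                         data, "noise")
            hits += f.pvalues["AT_GS"] < 0.05
        assert hits / n_sims <= 0.12


class TestCompareAIC:
    def test_best_model_delta_zero(self, fitted_battery):
        *_, fits = fitted_battery
        circ = [f for f in fits if f.response == "circularity"]
        table = compare_aic(circ)
        assert table["delta_AIC"].iloc[0] == 0.0
        assert (table["delta_AIC"] >= 0).all()
        assert table["delta_AIC"].is_monotonic_increasing

    def test_duplicate_best_model_also_zero(self, fitted_battery):
        *_, fits = fitted_battery
        circ = [f for f in fits if f.response == "circularity"]
        best = min(circ, key=lambda f: f.aic)
        table = compare_aic(circ + [best])
        assert (table["delta_AIC"] == 0.0).sum() >= 2

    def test_mixed_case_counts_rejected(self, fitted_battery):
        *_, fits = fitted_battery
        circ = [f for f in fits if f.response == "circularity"]
        import copy

        other = copy.copy(circ[1])
        other.n = circ[1].n - 3
        with pytest.raises(ComparabilityError):
            compare_aic([circ[0], other])

    def test_mixed_responses_rejected(self, fitted_battery):
        *_, fits = fitted_battery
        with pytest.raises(ComparabilityError):
            compare_aic([fits[0], next(f for f in fits if f.response == "aspect_ratio")])


class TestRegionTests:
    def test_cramers_v_perfect_association(self):
        chi2, p, v = cramers_v(np.array([[20, 0], [0, 20]]))
        assert v == pytest.approx(1.0)
        assert p < 1e-6

    def test_cramers_v_exact_independence(self):
        rows = np.array([10, 30])
        cols = np.array([5, 15, 20])
        table = np.outer(rows, cols) / 40.0
        chi2, p, v = cramers_v(table)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert v == pytest.approx(0.0, abs=1e-6)

    def test_report_structure(self, fitted_battery):
        spec, _, desc, regions, _ = fitted_battery
        d = desc.merge(regions.rename("region").reset_index(), on="id")
        table = pd.DataFrame(
            {"South": [10, 5], "Northeast": [3, 12]}, index=["Simplex", "Tenius"]
        )
        report = region_tests(d, type_table=table)
        assert 0 <= report["chi2"]["cramers_v"] <= 1
        assert "anova_circularity" in report and "tukey_circularity" in report
        assert set(report["ttests_circularity"]) == set(d["region"].unique())

    def test_small_region_excluded_with_warning(self, fitted_battery):
        spec, _, desc, regions, _ = fitted_battery
        d = desc.merge(regions.rename("region").reset_index(), on="id")
        extra = d.iloc[[0]].copy()
        extra["id"] = "lonely"
        extra["region"] = "Northwest"
        report = region_tests(pd.concat([d, extra], ignore_index=True))
        assert any("Northwest" in w for w in report["warnings"])

    def test_anova_null_p_roughly_uniform(self, rng):
        """Under the null, the region ANOVA rejects at ~5%."""
        hits = 0
        n_sims = 100
        regions = np.repeat(["A", "B", "C"], 20)
        for _ in range(n_sims):
            d = pd.DataFrame(
                {
                    "region": regions,
                    "circularity": rng.normal(size=60),
                    "aspect_ratio": rng.normal(size=60),
                }
            )
            report = region_tests(d)
            hits += report["anova_circularity"]["p"] < 0.05
        assert hits / n_sims <= 0.12


class TestTrend:
    def test_planted_linear_trend_recovered_exactly(self):
        years = np.arange(1950, 1970)
        d = pd.DataFrame(
            {
                "id": [f"l{i}" for i in range(20)],
                "year": years,
                "circularity": 0.2 + 0.003 * (years - 1950),
                "aspect_ratio": 3.0 - 0.01 * (years - 1950),
                "region": "South",
            }
        )
        t = trend(d)
        overall = t[(t["group"] == "overall") & (t["response"] == "circularity")]
        assert overall["slope"].iloc[0] == pytest.approx(0.003, abs=1e-9)
        ar = t[(t["group"] == "South") & (t["response"] == "aspect_ratio")]
        assert ar["slope"].iloc[0] == pytest.approx(-0.01, abs=1e-9)

    def test_group_with_two_years_skipped(self):
        d = pd.DataFrame(
            {
                "id": ["a", "b", "c", "d", "e", "f"],
                "year": [1950, 1951, 1952, 1960, 1960, 1961],
                "circularity": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
                "aspect_ratio": [1.0] * 6,
                "region": ["A", "A", "A", "B", "B", "B"],
            }
        )
        with pytest.warns(UserWarning, match="'B'"):
            t = trend(d)
        assert "B" not in set(t["group"])
        assert "A" in set(t["group"])

    def test_null_trend_rarely_significant(self, rng):
        hits = 0
        n_sims = 60
        for _ in range(n_sims):
            d = pd.DataFrame(
                {
                    "id": [f"l{i}" for i in range(50)],
                    "year": rng.integers(1920, 2020, 50),
                    "circularity": rng.normal(0.4, 0.1, 50),
                    "aspect_ratio": rng.normal(3, 1, 50),
                }
            )
            t = trend(d)
            p = t[(t["group"] == "overall") & (t["response"] == "circularity")]["p"].iloc[0]
            hits += p < 0.05
        assert hits / n_sims <= 0.15
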