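"""VPD, partial Spearman, regime models, Tukey HSD, interannual analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from borealfire.drivers import (
    annual_max_month_vpd,
    annual_trend,
    climatological_max_vpd,
    driver_correlations,
    fit_regime_models,
    interannual_sensitivity,
    lightning_climatology,
    partial_spearman,
    saturation_vapour_pressure,
    tukey_hsd,
    vpd,
    wilderness_fraction,
)


class TestVpd:
    def test_tetens_at_zero_celsius(self):
        assert saturation_vapour_pressure(0.0) == pytest.approx(0.61078,
                                                                abs=1e-12)

    def test_saturated_air_has_zero_deficit(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(-40, 35, size=100)
        np.testing.assert_allclose(vpd(t, t), 0.0, atol=1e-14)

    def test_direct_formula_oracle(self):
        expect = (0.61078 * np.exp(17.27 * 20 / (237.15 + 20))
                  - 0.61078 * np.exp(17.27 * 10 / (237.15 + 10)))
        assert vpd(20.0, 10.0) == pytest.approx(expect, rel=1e-12)

    def test_monotonicity(self):
        t = np.linspace(-20, 30, 80)
        assert np.all(np.diff(vpd(t, -25.0)) > 0)          # increasing in T
        td = np.linspace(-30, 10, 80)
        assert np.all(np.diff(vpd(15.0, td)) < 0)          # decreasing in Td

    def test_supersaturation_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="dewpoint exceeds"):
            assert vpd(10.0, 12.0) < 0
        assert vpd(10.0, 12.0, clamp=True) == 0.0

    def test_out_of_range_temperature(self):
        with pytest.raises(ValueError):
            saturation_vapour_pressure(-250.0)


class TestMaxVpdClimatology:
    def test_single_year_equals_max_month(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 2, size=(1, 12, 5, 5))
        out, month = climatological_max_vpd(v)
        np.testing.assert_allclose(out, v[0].max(axis=0))
        np.testing.assert_array_equal(month - 1, v[0].argmax(axis=0))

    def test_month_tie_goes_to_earliest(self):
        v = np.zeros((1, 12, 1, 1))
        v[0, 3] = v[0, 8] = 1.5
        _, month = climatological_max_vpd(v)
        assert month[0, 0] == 4

    def test_three_year_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 2, size=(3, 12, 4, 4))
        out, month = climatological_max_vpd(v)
        for i in range(4):
            for j in range(4):
                clim = [v[:, m, i, j].mean() for m in range(12)]
                m_star = int(np.argmax(clim))
                assert month[i, j] == m_star + 1
                assert out[i, j] == pytest.approx(clim[m_star])

    def test_annual_series_uses_climatological_month(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0, 2, size=(3, 12, 2, 2))
        ann = annual_max_month_vpd(v)
        _, month = climatological_max_vpd(v)
        for i in range(2):
            for j in range(2):
                np.testing.assert_allclose(ann[:, i, j],
                                           v[:, month[i, j] - 1, i, j])


class TestPartialSpearman:
    def test_no_covariates_reduces_to_spearman(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=80)
        y = 0.4 * x + rng.normal(size=80)
        res = partial_spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_rank_regression(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(30, 200)
        Z = rng.normal(size=(n, 2))
        x = Z @ [0.5, -0.3] + rng.normal(size=n)
        y = Z @ [-0.2, 0.4] + 0.3 * x + rng.normal(size=n)
        res = partial_spearman(x, y, Z)
        # independent oracle: residual correlation of ranks
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rz = np.column_stack([stats.rankdata(Z[:, 0]), stats.rankdata(Z[:, 1])])
        D = np.column_stack([np.ones(n), rz])
        ex = rx - D @ np.linalg.solve(D.T @ D, D.T @ rx)
        ey = ry - D @ np.linalg.solve(D.T @ D, D.T @ ry)
        expect = float(np.corrcoef(ex, ey)[0, 1])
        assert res.rho == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_conditional_independence_yields_small_rho(self, seed):
        rng = np.random.default_rng(10 + seed)
        n = 2000
        Z = rng.normal(size=(n, 2))
        x = Z @ [1.0, -0.5] + rng.normal(size=n)
        y = Z @ [0.7, 0.8] + rng.normal(size=n)
        res = partial_spearman(x, y, Z)
        assert abs(res.rho) < 0.08

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=50), rng.normal(size=50)
        z = rng.normal(size=50)
        with pytest.raises(ValueError, match="singular|collinear"):
            partial_spearman(x, y, np.column_stack([z, 2 * z]))

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(30), np.arange(30))

    def test_driver_correlation_matrix_layout(self):
        rng = np.random.default_rng(7)
        n = 200
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcy"))
        groups = pd.Series(np.where(np.arange(n) < 100, "G1", "G2"))
        out = driver_correlations(df, ["a", "b", "c"], ["y"], groups=groups)
        assert set(out["group"]) == {"all", "G1", "G2"}
        assert len(out) == 9
        assert ((out["rho"] <= 1) & (out["rho"] >= -1)).all()


class TestRegimeModels:
    def test_log_linear_response_recovered(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 2))
        y = 10 ** (0.5 + 0.4 * X[:, 0] - 0.3 * X[:, 1])
        df = pd.DataFrame({"y": y, "a": X[:, 0], "b": X[:, 1]})
        out = fit_regime_models(df, ["y"], ["a", "b"])
        assert out["r2"].iloc[0] > 0.99

    def test_null_response_low_r2(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"y": rng.uniform(0.1, 10, size=1000),
                           "a": rng.normal(size=1000),
                           "b": rng.normal(size=1000)})
        out = fit_regime_models(df, ["y"], ["a", "b"])
        assert out["r2"].iloc[0] < 0.02

    def test_nesting_never_lowers_r2(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"y": rng.uniform(0.1, 10, size=300),
                           "a": rng.normal(size=300),
                           "b": rng.normal(size=300)})
        r1 = fit_regime_models(df, ["y"], ["a"])["r2"].iloc[0]
        r2 = fit_regime_models(df, ["y"], ["a", "b"])["r2"].iloc[0]
        assert r2 >= r1 - 1e-12


class TestTukey:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=100)
        out = tukey_hsd(np.concatenate([v, v]),
                        np.repeat(["a", "b"], 100))
        assert out["p_adj"].iloc[0] > 0.99

    def test_extreme_separation_significant(self):
        rng = np.random.default_rng(12)
        v = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])
        out = tukey_hsd(v, np.repeat(["a", "b"], 50))
        assert out["p_adj"].iloc[0] < 1e-6

    def test_tiny_group_excluded(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 9.0])
        out = tukey_hsd(v, np.array(["a", "a", "b", "b", "c"]))
        assert set(out["group1"]) | set(out["group2"]) == {"a", "b"}

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(13)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = [rng.normal(size=20) for _ in range(3)]
            res = stats.tukey_hsd(*groups)
            if res.pvalue[np.triu_indices(3, 1)].min() < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.065


class TestInterannualAndTrends:
    def _annual(self, rho_sign=1.0, n_cells=6, n_years=6, fires_per_year=3):
        rows = []
        rng = np.random.default_rng(14)
        for c in range(n_cells):
            v = rng.uniform(0.3, 1.2, size=n_years)
            for yi in range(n_years):
                rows.append({"cell_id": c, "year": 2012 + yi,
                             "vpd_max_month": v[yi],
                             "burned_pct": rho_sign * v[yi] * 10,
                             "n_fires": fires_per_year,
                             "mean_size_km2": rho_sign * v[yi] * 5})
        return pd.DataFrame(rows)

    def test_monotone_coupling_gives_rho_one(self):
        annual = self._annual()
        groups = pd.Series("G", index=range(6))
        out = interannual_sensitivity(annual, groups,
                                      properties=["burned_pct", "mean_size_km2"])
        np.testing.assert_allclose(out["mean_rho"], 1.0, atol=1e-9)

    def test_cell_below_min_fires_excluded(self):
        annual = self._annual(fires_per_year=0)
        annual.loc[annual.cell_id == 0, "n_fires"] = [1, 1, 1, 1, 0, 0]
        groups = pd.Series("G", index=range(6))
        out = interannual_sensitivity(annual, groups, min_fires=5)
        assert out.empty       # 4 fires total everywhere -> no qualifying cell

    def test_trend_slope_and_symmetry(self):
        s = pd.Series([10.0, 20.0, 30.0, 40.0], index=[2012, 2013, 2014, 2015])
        slope, p = annual_trend(s)
        assert slope == pytest.approx(10.0)
        slope_neg, p_neg = annual_trend(-s)
        assert slope_neg == pytest.approx(-10.0)
        assert p == pytest.approx(p_neg)

    def test_trend_null_rejection_rate(self):
        rng = np.random.default_rng(15)
        rejected = 0
        for _ in range(1000):
            s = pd.Series(rng.normal(size=8), index=np.arange(2012, 2020))
            _, p = annual_trend(s)
            rejected += p < 0.05
        assert 0.03 <= rejected / 1000 <= 0.07

    def test_constant_year_vector_is_error(self):
        with pytest.raises(ValueError):
            annual_trend(pd.Series([1.0, 2.0, 3.0], index=[2012, 2012, 2012]))


class TestAggregationHelpers:
    def test_lightning_climatology_uses_march_to_october(self):
        v = np.zeros((2, 12, 3, 3))
        v[:, 2:10] = 1.0        # March..October
        v[:, 0] = 99.0          # January must not leak in
        out = lightning_climatology(v)
        np.testing.assert_allclose(out, 1.0)

    def test_wilderness_counts_only_exact_zero(self):
        hfp = np.array([[0.0, 0.0, 1e-9], [3.0, 0.0, 7.0]])
        assert wilderness_fraction(hfp) == pytest.approx(3 / 6)
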