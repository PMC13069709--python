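"""Within-estimator fixed effects and CR1 cluster-robust inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urbexpo.fe_model import (FixedEffectsOLS, ModelSpec, RankDeficientError,
                              SingleClusterError, cluster_ci,
                              cluster_robust_vcov, standardized_coefficient,
                              within_transform)


def _toy_panel(seed=0, n_groups=12, per_group=15):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), per_group)
    n = g.size
    x = rng.normal(size=n) + 0.8 * rng.normal(size=n_groups)[g]
    z = rng.normal(size=n)
    y = 2.0 * x - 1.0 * z + rng.normal(size=n_groups)[g] + rng.normal(size=n)
    return pd.DataFrame({"y": y, "x": x, "z": z,
                         "fe": [f"g{i}" for i in g],
                         "cl": [f"c{i % 6}" for i in g]})


class TestWithinTransform:
    def test_group_means_are_zero(self):
        d = _toy_panel()
        y_t, X_t, _ = within_transform(d["y"].to_numpy(), d[["x", "z"]],
                                       d["fe"])
        for col in X_t.columns:
            gm = X_t[col].groupby(d["fe"].to_numpy()).mean()
            assert np.abs(gm).max() < 1e-12
        assert np.abs(pd.Series(y_t).groupby(
            d["fe"].to_numpy()).mean()).max() < 1e-12

    def test_group_constant_column_dropped_with_warning(self):
        d = _toy_panel()
        d["const_in_g"] = d["fe"].map(lambda s: hash(s) % 7).astype(float)
        with pytest.warns(UserWarning, match="const_in_g"):
            _, X_t, dropped = within_transform(
                d["y"].to_numpy(), d[["x", "const_in_g"]], d["fe"])
        assert dropped == ["const_in_g"]
        assert list(X_t.columns) == ["x"]

    def test_slope_equals_dummy_variable_normal_equations(self):
        d = _toy_panel(3)
        y_t, X_t, _ = within_transform(d["y"].to_numpy(), d[["x", "z"]],
                                       d["fe"])
        beta_within = np.linalg.lstsq(X_t.to_numpy(), y_t, rcond=None)[0]
        # independent oracle: explicit dummy design, normal equations
        D = pd.get_dummies(d["fe"], dtype=float).to_numpy()
        X_full = np.column_stack([d[["x", "z"]].to_numpy(), D])
        XtX = X_full.T @ X_full
        beta_full = np.linalg.solve(XtX, X_full.T @ d["y"].to_numpy())
        np.testing.assert_allclose(beta_within, beta_full[:2], rtol=1e-8)


class TestClusterRobustVcov:
    def test_singleton_clusters_reduce_to_hc1(self):
        d = _toy_panel(1)
        X = d[["x", "z"]].to_numpy()
        beta = np.linalg.lstsq(X, d["y"].to_numpy(), rcond=None)[0]
        u = d["y"].to_numpy() - X @ beta
        V = cluster_robust_vcov(X, u, np.arange(len(d)))
        n, k = X.shape
        bread = np.linalg.inv(X.T @ X)
        hc1 = (n / (n - k)) * bread @ (X * u[:, None] ** 2).T @ X @ bread
        np.testing.assert_allclose(V, hc1, atol=1e-10)

    def test_single_cluster_is_an_error(self):
        d = _toy_panel(2)
        X = d[["x"]].to_numpy()
        with pytest.raises(SingleClusterError):
            cluster_robust_vcov(X, d["y"].to_numpy(), np.zeros(len(d)))

    def test_homoskedastic_independent_matches_classical_se(self):
        # mean cluster-robust SE over replicates ~ classical OLS SE
        rng = np.random.default_rng(8)
        n, G = 300, 30
        ses, classical = [], []
        for _ in range(300):
            x = rng.normal(size=n)
            y = 1.5 * x + rng.normal(size=n)
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            u = y - X @ beta
            cl = rng.integers(0, G, size=n)
            V = cluster_robust_vcov(X, u, cl)
            ses.append(np.sqrt(V[1, 1]))
            s2 = u @ u / (n - 2)
            classical.append(np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1]))
        assert np.mean(ses) == pytest.approx(np.mean(classical), rel=0.05)

    def test_coverage_with_intracluster_correlation(self):
        """CR1 + t(G-1) covers ~95% under ICC 0.2, G=33; naive does not."""
        rng = np.random.default_rng(21)
        G, m, icc = 33, 10, 0.2
        n = G * m
        cover_cr, cover_naive = [], []
        for _ in range(500):
            cl = np.repeat(np.arange(G), m)
            x = rng.normal(size=G)[cl] + rng.normal(size=n)
            e = (np.sqrt(icc) * rng.normal(size=G)[cl]
                 + np.sqrt(1 - icc) * rng.normal(size=n))
            y = 1.0 * x + e
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            u = y - X @ beta
            se_cr = np.sqrt(cluster_robust_vcov(X, u, cl)[1, 1])
            lo, hi = cluster_ci(beta[1], se_cr, G)
            cover_cr.append(lo <= 1.0 <= hi)
            s2 = u @ u / (n - 2)
            se_cl = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            z = stats.norm.ppf(0.975)
            cover_naive.append(beta[1] - z * se_cl <= 1.0
                               <= beta[1] + z * se_cl)
        assert 0.92 <= np.mean(cover_cr) <= 0.98
        assert np.mean(cover_naive) < 0.92


class TestClusterCI:
    @pytest.mark.parametrize("beta,se,lo,hi", [
        (0.150, 0.055, 0.038, 0.262),   # published Model 2 inference
        (0.142, 0.056, 0.028, 0.256),   # published Model 3 inference
    ])
    def test_reconstructs_published_intervals(self, beta, se, lo, hi):
        ci_lo, ci_hi = cluster_ci(beta, se, n_clusters=33)
        assert ci_lo == pytest.approx(lo, abs=5e-4)
        assert ci_hi == pytest.approx(hi, abs=5e-3)

    def test_uses_t_not_normal_critical_values(self):
        lo_t, _ = cluster_ci(0.0, 1.0, n_clusters=33)
        assert lo_t == pytest.approx(-stats.t.ppf(0.975, 32))
        assert abs(lo_t) > stats.norm.ppf(0.975)


class TestStandardizedCoefficient:
    def test_published_per_sd_effect(self):
        # 0.150 ng/mL per 1,000 m^2 at SD ~11.9 thousand m^2 -> ~1.78 ng/mL
        per_sd = standardized_coefficient(0.150, 11.9)
        assert per_sd == pytest.approx(1.78, abs=0.01)

    def test_unit_sd_is_identity(self):
        assert standardized_coefficient(0.37, 1.0) == pytest.approx(0.37)

    def test_matches_refit_on_z_scored_data(self, analysis_table,
                                            spec_subzone):
        res = FixedEffectsOLS(analysis_table, spec_subzone).fit()
        d = analysis_table.copy()
        for col in ("PFBS", "exposure_k"):
            d[col] = (d[col] - d[col].mean()) / d[col].std(ddof=1)
        res_z = FixedEffectsOLS(d, spec_subzone).fit()
        assert res.standardized_beta() == pytest.approx(res_z.beta, rel=1e-8)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            standardized_coefficient(1.0, 0.0)


class TestFixedEffectsOLS:
    def test_matches_statsmodels_dummy_cluster_ols(self, analysis_table,
                                                   spec_subzone):
        """Full independent route: statsmodels OLS with explicit subzone
        dummies and clustered covariance reproduces beta and SE."""
        import statsmodels.formula.api as smf
        res = FixedEffectsOLS(analysis_table, spec_subzone).fit()
        f = ("PFBS ~ exposure_k + age + parity + C(ethnicity) + C(education)"
             " + C(occupation) + C(housing_type) + C(marital_status)"
             " + C(birthplace) + C(subzone_id)")
        sm = smf.ols(f, data=analysis_table).fit(
            cov_type="cluster",
            cov_kwds={"groups": analysis_table["planning_area_id"]},
            use_t=True)
        assert res.beta == pytest.approx(sm.params["exposure_k"], rel=1e-8)
        assert res.se == pytest.approx(sm.bse["exposure_k"], rel=1e-8)

    def test_scaling_equivariance(self, analysis_table, spec_subzone):
        res = FixedEffectsOLS(analysis_table, spec_subzone).fit()
        d = analysis_table.copy()
        d["exposure_k"] = d["exposure_k"] * 10.0
        res10 = FixedEffectsOLS(d, spec_subzone).fit()
        assert res10.beta == pytest.approx(res.beta / 10.0, rel=1e-10)
        assert res10.t_stat == pytest.approx(res.t_stat, rel=1e-10)
        assert res10.p_value == pytest.approx(res.p_value, rel=1e-10)

    def test_df_is_clusters_minus_one(self, analysis_table, spec_subzone):
        res = FixedEffectsOLS(analysis_table, spec_subzone).fit()
        assert res.n_clusters == 33
        assert res.df_inference == 32
        assert res.ci_low <= res.beta <= res.ci_high

    def test_duplicate_exposure_column_names_collinearity(self,
                                                          analysis_table,
                                                          spec_subzone):
        d = analysis_table.copy()
        d["copy_of_exposure"] = d["exposure_k"]
        spec = ModelSpec("PFBS", "exposure_k",
                         spec_subzone.covariates + ("copy_of_exposure",),
                         "subzone_id", "planning_area_id")
        with pytest.raises(RankDeficientError, match="copy_of_exposure"):
            FixedEffectsOLS(d, spec).fit()

    def test_listwise_deletion_of_missing_income(self, analysis_table,
                                                 spec_subzone):
        spec3 = ModelSpec("PFBS", "exposure_k",
                          spec_subzone.covariates + ("income",),
                          "subzone_id", "planning_area_id")
        res = FixedEffectsOLS(analysis_table, spec3).fit()
        n_missing = analysis_table["income"].isna().sum()
        assert n_missing > 0
        assert res.nobs == len(analysis_table) - n_missing
        assert res.n_dropped_missing == n_missing

    def test_summary_mentions_key_inference_facts(self, analysis_table,
                                                  spec_subzone):
        txt = FixedEffectsOLS(analysis_table, spec_subzone).fit().summary()
        assert "G=33" in txt and "exposure_k" in txt and "CR1" in txt
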