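"""Within/RE/OLS estimators against brute-force oracles, and the cluster-robust
sandwich variance."""

import warnings

import numpy as np
import pandas as pd
import pytest

import distresscost as dc
from distresscost.panel_estimators import (Design, DesignSpec, build_design,
                                           cluster_robust_vcov, fit,
                                           fit_pooled_ols, fit_random_effects,
                                           fit_within, within_transform)
from conftest import make_panel


def _design_from_arrays(y, X, ids, columns=None, estimator="FE"):
    columns = columns or [f"x{j}" for j in range(X.shape[1])]
    labels, codes = np.unique(ids, return_inverse=True)
    spec = DesignSpec(outcome="y", exposure=columns[0], controls=(),
                      estimator=estimator)
    return Design(y=np.asarray(y, float), X=np.asarray(X, float),
                  columns=columns, clusters=codes, cluster_labels=labels,
                  row_index=pd.MultiIndex.from_arrays(
                      [ids, np.arange(len(y))], names=["id", "wave"]),
                  exposure_cols=[columns[0]], k10=np.full(len(y), 15),
                  spec=spec)


def _random_panel(rng, n_women=None):
    n_women = n_women or int(rng.integers(4, 21))
    rows = []
    for i in range(n_women):
        T = int(rng.integers(2, 6))
        rows += [(i, t) for t in range(T)]
    ids = np.array([r[0] for r in rows])
    n = len(ids)
    X = rng.standard_normal((n, 3))
    u = rng.standard_normal(n_women)[ids]
    y = 1.5 * X[:, 0] - 0.7 * X[:, 1] + 0.2 * X[:, 2] + u + rng.standard_normal(n)
    return y, X, ids


def _lsdv_oracle(y, X, ids):
    """Brute-force dummy-variable least squares for the within estimator."""
    dummies = (ids[:, None] == np.unique(ids)[None, :]).astype(float)
    Z = np.column_stack([X, dummies])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return beta[:X.shape[1]]


class TestWithin:
    def test_two_point_within_slope(self):
        d = _design_from_arrays([1.0, 3.0], np.array([[0.0], [1.0]]), np.array([1, 1]))
        with pytest.warns(UserWarning, match="single cluster"):
            f = fit_within(d)
        assert f.params["x0"] == pytest.approx(2.0)

    def test_equals_lsdv_on_random_panels(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            y, X, ids = _random_panel(rng)
            f = fit_within(_design_from_arrays(y, X, ids))
            oracle = _lsdv_oracle(y, X, ids)
            np.testing.assert_allclose(f.params.to_numpy(), oracle, rtol=1e-8)

    def test_matches_statsmodels_lsdv(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        y, X, ids = _random_panel(rng, n_women=12)
        f = fit_within(_design_from_arrays(y, X, ids))
        dummies = pd.get_dummies(pd.Series(ids), dtype=float)
        sm_fit = sm.OLS(y, np.column_stack([X, dummies])).fit()
        np.testing.assert_allclose(f.params.to_numpy(), sm_fit.params[:3], rtol=1e-8)

    def test_demeaned_regressors_have_zero_group_means(self):
        rng = np.random.default_rng(1)
        y, X, ids = _random_panel(rng)
        labels, codes = np.unique(ids, return_inverse=True)
        Xw = within_transform(X, codes, len(labels))
        for g in range(len(labels)):
            np.testing.assert_allclose(Xw[codes == g].mean(axis=0), 0, atol=1e-10)

    def test_constant_within_exposure_rejected(self):
        ids = np.array([1, 1, 2, 2])
        X = np.array([[1.0], [1.0], [2.0], [2.0]])  # varies only between women
        y = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="within"):
            fit_within(_design_from_arrays(y, X, ids))

    def test_intercept_shift_leaves_fe_slopes_unchanged(self):
        rng = np.random.default_rng(2)
        y, X, ids = _random_panel(rng)
        f1 = fit_within(_design_from_arrays(y, X, ids))
        f2 = fit_within(_design_from_arrays(y + 7.5, X, ids))
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self):
        rng = np.random.default_rng(3)
        y, X, ids = _random_panel(rng)
        labels, codes = np.unique(ids, return_inverse=True)
        f = fit_within(_design_from_arrays(y, X, ids))
        Xw = within_transform(X, codes, len(labels))
        assert np.abs(Xw.T @ f.resid).max() < 1e-8 * len(y)


class TestPooledAndRE:
    def test_ols_intercept_shift_moves_only_intercept(self):
        rng = np.random.default_rng(4)
        y, X, ids = _random_panel(rng)
        f1 = fit_pooled_ols(_design_from_arrays(y, X, ids))
        f2 = fit_pooled_ols(_design_from_arrays(y + 3.0, X, ids))
        np.testing.assert_allclose(f1.params[:-1], f2.params[:-1], atol=1e-10)
        assert f2.params["const"] - f1.params["const"] == pytest.approx(3.0)

    def test_re_equals_ols_when_no_individual_variance(self):
        rng = np.random.default_rng(6)
        n_women, T = 60, 4
        ids = np.repeat(np.arange(n_women), T)
        X = rng.standard_normal((n_women * T, 2))
        y = 1.0 * X[:, 0] + 0.5 * X[:, 1] + rng.standard_normal(n_women * T)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_re = fit_random_effects(_design_from_arrays(y, X, ids))
        f_ols = fit_pooled_ols(_design_from_arrays(y, X, ids))
        np.testing.assert_allclose(f_re.params.to_numpy(), f_ols.params.to_numpy(),
                                   atol=2e-2)

    def test_re_approaches_fe_with_large_individual_variance(self):
        rng = np.random.default_rng(7)
        n_women, T = 80, 5
        ids = np.repeat(np.arange(n_women), T)
        X = rng.standard_normal((n_women * T, 1)) + rng.standard_normal(n_women)[ids]
        u = 50.0 * rng.standard_normal(n_women)[ids]
        y = 2.0 * X[:, 0] + u + 0.5 * rng.standard_normal(n_women * T)
        f_re = fit_random_effects(_design_from_arrays(y, X, ids))
        f_fe = fit_within(_design_from_arrays(y, X, ids))
        assert f_re.params["x0"] == pytest.approx(f_fe.params["x0"], abs=0.02)
        assert f_re.variance_components["theta_range"][0] > 0.95


class TestClusterVcov:
    def test_singleton_clusters_equal_hc1(self):
        rng = np.random.default_rng(8)
        n = 60
        X = np.column_stack([rng.standard_normal(n), np.ones(n)])
        y = X @ np.array([1.0, 0.5]) + rng.standard_normal(n)
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        e = y - X @ b
        V = cluster_robust_vcov(X, e, np.arange(n))
        xtx_inv = np.linalg.inv(X.T @ X)
        hc1 = (n / (n - 2)) * xtx_inv @ (X * e[:, None] ** 2).T @ X @ xtx_inv
        np.testing.assert_allclose(V, hc1, atol=1e-10)

    def test_duplicating_clusters_changes_only_small_sample_factor(self):
        rng = np.random.default_rng(9)
        n, G = 40, 10
        cl = np.repeat(np.arange(G), n // G)
        X = np.column_stack([rng.standard_normal(n), np.ones(n)])
        e = rng.standard_normal(n)
        V1 = cluster_robust_vcov(X, e, cl)
        V2 = cluster_robust_vcov(np.vstack([X, X]), np.concatenate([e, e]),
                                 np.concatenate([cl, cl]))
        k = X.shape[1]
        f1 = (G / (G - 1)) * ((n - 1) / (n - k))
        f2 = (G / (G - 1)) * ((2 * n - 1) / (2 * n - k))
        # doubling rows halves the bread twice and quadruples the meat, so the
        # unscaled sandwich is invariant; only the N-dependent factor moves
        np.testing.assert_allclose(V2, V1 * (f2 / f1), rtol=1e-10)

    def test_single_cluster_rejected(self):
        X = np.ones((5, 1))
        with pytest.raises(ValueError):
            cluster_robust_vcov(X, np.ones(5), np.zeros(5))

    def test_ci_coverage_on_independent_data(self):
        # independent homoskedastic data, arbitrary cluster assignment:
        # nominal 95% intervals should cover the truth ~95% of the time
        rng = np.random.default_rng(10)
        G, T, beta = 50, 4, 0.5
        hits, reps = 0, 1000
        for _ in range(reps):
            cl = np.repeat(np.arange(G), T)
            x = rng.standard_normal(G * T)
            y = beta * x + rng.standard_normal(G * T)
            X = np.column_stack([x, np.ones(G * T)])
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            V = cluster_robust_vcov(X, y - X @ b, cl)
            hits += abs(b[0] - beta) <= 1.96 * np.sqrt(V[0, 0])
        assert 0.93 <= hits / reps <= 0.97


class TestBuildDesign:
    def _tiny(self):
        panel = make_panel([
            {"id": 1, "wave": 1, "k10": 15, "healthcare_card": 0},
            {"id": 1, "wave": 2, "k10": 25, "healthcare_card": 1},
            {"id": 2, "wave": 1, "k10": 30, "healthcare_card": 1},
            {"id": 2, "wave": 2, "k10": 35, "healthcare_card": 0},
        ])
        costs = pd.DataFrame({"id": [1, 1, 2, 2], "wave": [1, 2, 1, 2],
                              "total": [100.0, 0.0, 250.0, 300.0]})
        return panel, costs

    def test_expected_columns(self):
        panel, costs = self._tiny()
        spec = DesignSpec(outcome="positive_total", exposure="k10",
                          controls=("healthcare_card",))
        d = build_design(panel, costs, spec)
        assert d.columns == ["k10", "healthcare_card", "year[2014]"]
        assert d.n == 4 and d.n_clusters == 2

    def test_log_outcome_drops_zero_cost_rows(self):
        panel, costs = self._tiny()
        spec = DesignSpec(outcome="log_total", exposure="k10",
                          controls=("healthcare_card",))
        d = build_design(panel, costs, spec)
        assert d.n == 3
        np.testing.assert_allclose(sorted(d.y), np.log([100.0, 250.0, 300.0]))

    def test_missing_covariate_row_deleted_and_counted(self):
        panel, costs = self._tiny()
        panel.loc[0, "age"] = np.nan
        spec = DesignSpec(outcome="positive_total", exposure="k10",
                          controls=("age",))
        d = build_design(panel, costs, spec)
        assert d.n == 3 and d.n_dropped_missing == 1

    def test_categoricals_expand_against_reference(self):
        panel, costs = self._tiny()
        panel["marital"] = ["never_married", "married", "married", "defacto"]
        spec = DesignSpec(outcome="positive_total", exposure="k10",
                          controls=("marital",))
        d = build_design(panel, costs, spec)
        # sorted first level 'defacto' is the reference
        assert "marital[married]" in d.columns
        assert "marital[defacto]" not in d.columns

    def test_exposure_in_controls_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec(outcome="log_total", exposure="k10", controls=("k10",))


class TestParameterRecoveryQuick:
    def test_fe_recovers_dgp_slope_within_two_se(self, default_sim):
        sim = default_sim
        spec = DesignSpec(outcome="log_total", exposure="k10", estimator="FE")
        f = fit(build_design(sim.panel, sim.costs, spec))
        truth = sim.truth.config.beta_k10
        assert abs(f.params["k10"] - truth) <= 2 * f.se["k10"]
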