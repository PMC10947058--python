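"""Two-part model: smearing, dollar-scale predictions, incremental effects,
and the cluster bootstrap."""

import warnings

import numpy as np
import pandas as pd
import pytest

import distresscost as dc
from distresscost.panel_estimators import DesignSpec
from distresscost.two_part_effects import (cluster_bootstrap, duan_smearing,
                                           fit_two_part, incremental_effect,
                                           predict_unconditional)


class TestDuanSmearing:
    def test_zero_residuals_give_unit_factor(self):
        t = duan_smearing(np.zeros(10), np.array(["a"] * 10))
        assert t.factors["a"] == pytest.approx(1.0)

    def test_two_point_example(self):
        t = duan_smearing(np.log([2.0, 0.5]), np.array(["g", "g"]))
        assert t.factors["g"] == pytest.approx(1.25)

    def test_lognormal_closed_form(self):
        rng = np.random.default_rng(0)
        r = rng.normal(0, 0.5, size=100_000)
        t = duan_smearing(r, np.array(["all"] * len(r)))
        assert t.factors["all"] == pytest.approx(np.exp(0.125), abs=0.02)

    def test_overall_is_size_weighted_group_mean(self):
        rng = np.random.default_rng(1)
        r = rng.normal(0, 0.3, size=500)
        g = rng.choice(["a", "b", "c"], size=500, p=[0.5, 0.3, 0.2])
        t = duan_smearing(r, g)
        assert t.overall == pytest.approx(np.mean(np.exp(r)))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            duan_smearing(np.zeros(3), np.array(["a"] * 4))


@pytest.fixture(scope="module")
def noise_free():
    """Deterministic DGP: cost = exp(alpha + beta * K10), everyone positive."""
    cfg = dc.SimConfig(n_women=60, seed=17, sigma_u=0.0,
                       sigma_eps_by_level=(0, 0, 0, 0), zero_mass_target=0.0,
                       covariate_effects_scale=0.0, year_effect_per_wave=0.0,
                       attrition_rate_per_wave=0.0)
    sim = dc.simulate_panel(cfg, with_claims=False)
    spec = DesignSpec(outcome="total", exposure="k10", estimator="FE", controls=())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tpf = fit_two_part(sim.panel, sim.costs, spec)
    return cfg, sim, tpf


@pytest.fixture(scope="module")
def default_fit(default_sim):
    spec = DesignSpec(outcome="total", exposure="k10", estimator="FE")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_two_part(default_sim.panel, default_sim.costs, spec)


class TestNoiseFreeFixture:
    def test_part2_recovers_slope_exactly(self, noise_free):
        cfg, _, tpf = noise_free
        assert tpf.part2.params["k10"] == pytest.approx(cfg.beta_k10, abs=1e-10)

    def test_residuals_zero_and_smearing_unity(self, noise_free):
        _, _, tpf = noise_free
        assert np.abs(tpf.part2.resid).max() < 1e-10
        for f in tpf.smearing.factors.values():
            assert f == pytest.approx(1.0, abs=1e-10)

    def test_predictions_equal_generating_values(self, noise_free):
        cfg, sim, tpf = noise_free
        pred = predict_unconditional(tpf)
        np.testing.assert_allclose(pred, sim.costs["total"], rtol=1e-6)

    def test_effect_equals_closed_form_contrast(self, noise_free):
        cfg, _, tpf = noise_free
        eff = incremental_effect(tpf, (22, 23))
        expect = np.exp(cfg.alpha_cost) * (np.exp(23 * cfg.beta_k10)
                                           - np.exp(22 * cfg.beta_k10))
        assert eff.conditional == pytest.approx(expect, rel=1e-6)
        assert eff.unconditional == pytest.approx(expect, rel=1e-6)


class TestEffects:
    def test_equal_contrast_is_exactly_zero(self, default_fit):
        with pytest.warns(UserWarning, match="equal"):
            eff = incremental_effect(default_fit, (25, 25))
        assert eff.conditional == 0.0 and eff.unconditional == 0.0

    def test_unconditional_never_exceeds_conditional_prediction(self, default_fit):
        # part-1 probabilities are clipped to [0, 1], so the unconditional
        # prediction is a shrinkage of the conditional one
        cond = predict_unconditional(default_fit, exposure_value=30)
        tpf = default_fit
        from distresscost.two_part_effects import (_counterfactual_X,
                                                   _counterfactual_group,
                                                   _linear_predictor)
        d1 = tpf.design1
        Xc = _counterfactual_X(d1.X, d1.columns, "k10", 30)
        s = tpf.smearing.lookup(_counterfactual_group("k10", 30, tpf.spec.cutoffs,
                                                      "level"))
        lvl = np.exp(_linear_predictor(d1, tpf.part2, Xc)) * s
        assert (cond <= lvl + 1e-9).all()
        assert (cond >= 0).all()

    def test_mean_prediction_close_to_sample_mean(self, default_sim, default_fit):
        pred = predict_unconditional(default_fit)
        sample = default_sim.costs["total"].mean()
        assert abs(pred.mean() - sample) / sample < 0.02

    def test_unconditional_effect_recovers_dgp_truth(self, default_sim, default_fit):
        truth = default_sim.truth.true_effects(22, 23)
        eff = incremental_effect(default_fit, (22, 23))
        # Monte-Carlo tolerance: one realization at 2,000 women
        assert eff.unconditional == pytest.approx(truth["unconditional"], rel=0.5)
        assert eff.conditional == pytest.approx(truth["conditional"], rel=0.5)

    def test_invariant_to_row_and_cluster_relabeling(self, default_sim):
        sim = default_sim
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(sim.panel))
        panel2 = sim.panel.iloc[perm].reset_index(drop=True)
        costs2 = sim.costs.iloc[perm].reset_index(drop=True)
        relabel = {i: 10_000_000 - i for i in sim.panel["id"].unique()}
        panel3 = panel2.assign(id=panel2["id"].map(relabel))
        costs3 = costs2.assign(id=costs2["id"].map(relabel))
        spec = DesignSpec(outcome="total", exposure="distress_dummy", estimator="FE")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e1 = incremental_effect(fit_two_part(sim.panel, sim.costs, spec), (0, 1))
            e2 = incremental_effect(fit_two_part(panel3, costs3, spec), (0, 1))
        assert e1.unconditional == pytest.approx(e2.unconditional, rel=1e-8)

    def test_level_exposure_effects_increase_with_severity(self, default_sim):
        spec = DesignSpec(outcome="total", exposure="level_dummies", estimator="FE")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tpf = fit_two_part(default_sim.panel, default_sim.costs, spec)
        effs = {lv: incremental_effect(tpf, ("none", lv)).unconditional
                for lv in ("mild", "moderate", "severe")}
        assert effs["mild"] < effs["moderate"] < effs["severe"]


class TestBootstrap:
    def test_seed_determinism(self, claims_sim):
        spec = DesignSpec(outcome="total", exposure="distress_dummy", estimator="FE")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tpf = fit_two_part(claims_sim.panel, claims_sim.costs, spec)
        b1 = cluster_bootstrap(tpf, (0, 1), B=5, seed=42)
        b2 = cluster_bootstrap(tpf, (0, 1), B=5, seed=42)
        assert b1.unconditional_se == b2.unconditional_se
        assert b1.conditional_ci == b2.conditional_ci

    def test_identical_women_give_zero_se(self):
        # clone one woman's history: resampling cannot create variability
        waves = [1, 2, 3, 4]
        k10s = [15, 22, 28, 33]
        rows, cost_rows = [], []
        for i in range(1, 13):
            for w, k in zip(waves, k10s):
                rows.append({"id": i, "wave": w, "year": 2012 + w, "k10": k,
                             "age": 20 + w, "marital": "never_married",
                             "education": "degree", "unemployed": 0,
                             "income_mgmt": 0, "healthcare_card": 0,
                             "residence": "metro", "state": "NSW",
                             "survey_month": 5})
                cost_rows.append({"id": i, "wave": w, "total": 100.0 * w})
        panel = pd.DataFrame(rows)
        costs = pd.DataFrame(cost_rows)
        spec = DesignSpec(outcome="total", exposure="k10", estimator="FE",
                          controls=())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tpf = fit_two_part(panel, costs, spec)
            b = cluster_bootstrap(tpf, (22, 23), B=10, seed=0)
        assert b.unconditional_se == pytest.approx(0.0, abs=1e-10)

    def test_invalid_inputs_rejected(self, claims_sim):
        spec = DesignSpec(outcome="total", exposure="distress_dummy", estimator="FE")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tpf = fit_two_part(claims_sim.panel, claims_sim.costs, spec)
        with pytest.raises(ValueError):
            cluster_bootstrap(tpf, (0, 1), B=1, seed=0)

    def test_fast_path_matches_full_pipeline_point_estimate(self, claims_sim):
        # the replicate engine run on the identity resample must reproduce the
        # full-pipeline point estimate exactly
        from distresscost.two_part_effects import _BootState
        spec = DesignSpec(outcome="total", exposure="distress_dummy", estimator="FE")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tpf = fit_two_part(claims_sim.panel, claims_sim.costs, spec)
        eff = incremental_effect(tpf, (0, 1))
        state = _BootState(tpf, (0, 1))
        rows = np.concatenate(state.rows_by_cluster)
        sizes = [len(r) for r in state.rows_by_cluster]
        new_clusters = np.repeat(np.arange(state.n_clusters), sizes)
        cond, uncond = state.point(rows, new_clusters)
        assert cond == pytest.approx(eff.conditional, rel=1e-8)
        assert uncond == pytest.approx(eff.unconditional, rel=1e-8)


class TestMonthlyProfile:
    def test_front_loaded_costs_show_largest_early_window_effect(self):
        from distresscost.extrapolation_report import _monthly_stage
        cfg = dc.SimConfig(n_women=600, seed=9, monthly_frontload=0.6)
        sim = dc.simulate_panel(cfg)
        defl = dc.DeflatorTable(index=dict(cfg.cpi_by_year))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = _monthly_stage(sim.panel, sim.claims, defl,
                                 [1, 3, 12]).set_index("window_months")
        assert tab.loc[1, "log_coef_k10"] > tab.loc[12, "log_coef_k10"]
        assert tab.loc[3, "log_coef_k10"] > tab.loc[12, "log_coef_k10"]
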