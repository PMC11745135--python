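"""Bayesian phylogenetic mixed model: sampler, oracle, rankings."""

import numpy as np
import pandas as pd
import pytest

import scorpsize as sz
from scorpsize.pmm import PhylogeneticMixedModel
from scorpsize.simulate import simulate_pmm_dataset


@pytest.fixture(scope="module")
def tree80():
    return sz.simulate_tree(80, seed=51)


@pytest.fixture(scope="module")
def data80(tree80):
    return simulate_pmm_dataset(tree80, a=2.13, b=0.95, seed=52)


@pytest.fixture(scope="module")
def fit80(tree80, data80, small_pmm_settings):
    spec = sz.ModelSpec("toL", ("met5L",), mcmc=small_pmm_settings)
    return sz.fit_pmm(data80, tree80, spec, seed=53)


class TestBookkeeping:
    def test_study_settings_retain_900_draws(self):
        assert sz.MCMCSettings().n_retained == 900

    def test_draw_count_matches_settings(self, fit80, small_pmm_settings):
        assert len(fit80.draws_) == small_pmm_settings.n_retained
        assert (fit80.draws_[["var_phylo", "var_species", "var_resid"]] > 0
                ).all().all()

    def test_summary_orders_bounds(self, fit80):
        s = fit80.summary_
        assert (s["lower"] <= s["mean"]).all()
        assert (s["mean"] <= s["upper"]).all()
        assert (s["ess"] <= len(fit80.draws_) * 1.05).all()

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            sz.MCMCSettings(iterations=100, burn_in=200, thin=10)
        with pytest.raises(ValueError):
            sz.ModelSpec("toL", ("toL",))

    def test_deterministic_under_seed(self, tree80, data80):
        spec = sz.ModelSpec("toL", ("met5L",),
                            mcmc=sz.MCMCSettings(600, 100, 5))
        a = sz.fit_pmm(data80, tree80, spec, seed=5)
        b = sz.fit_pmm(data80, tree80, spec, seed=5)
        pd.testing.assert_frame_equal(a.draws_, b.draws_)


class TestAgainstOracles:
    def test_noiseless_pgls_exact(self, tree80):
        data = simulate_pmm_dataset(
            tree80, a=1.7, b=0.9, sigma2_phylo=0.0, sigma2_species=0.0,
            sigma2_resid=1e-12, seed=60,
        )
        spec = sz.ModelSpec("toL", ("met5L",))
        res = sz.fit_pgls_ml(data, tree80, spec)
        assert res.coef["(Intercept)"] == pytest.approx(1.7, abs=1e-6)
        assert res.coef["met5L"] == pytest.approx(0.9, abs=1e-6)

    def test_pgls_without_phylo_signal_equals_ols(self, star_tree):
        rng = np.random.default_rng(61)
        x = rng.normal(2.0, 0.5, size=8)
        y = 1.0 + 0.8 * x + rng.normal(0, 0.05, size=8)
        idx = pd.MultiIndex.from_tuples(
            [(s, sex) for sex in ["female", "male"]
             for s in star_tree.tip_labels],
            names=["species", "sex"],
        )
        frame = pd.DataFrame(
            {"toL": np.concatenate([y, y + 0.01]),
             "met5L": np.concatenate([x, x])},
            index=idx,
        )
        data = sz.TraitMatrix(frame, scale="log")
        spec = sz.ModelSpec("toL", ("met5L",))
        res = sz.fit_pgls_ml(data, star_tree, spec)
        X = np.column_stack([np.ones(16), frame["met5L"]])
        beta_ols = np.linalg.lstsq(X, frame["toL"], rcond=None)[0]
        np.testing.assert_allclose(
            res.coef.to_numpy(), beta_ols, atol=5e-3
        )

    def test_sampler_matches_ols_on_star_tree(self, star_tree,
                                              small_pmm_settings):
        rng = np.random.default_rng(62)
        n = 8
        x = rng.normal(2.0, 0.6, size=2 * n)
        y = 0.5 + 1.1 * x + rng.normal(0, 0.03, size=2 * n)
        idx = pd.MultiIndex.from_tuples(
            [(s, sex) for sex in ["female", "male"]
             for s in star_tree.tip_labels],
            names=["species", "sex"],
        )
        data = sz.TraitMatrix(
            pd.DataFrame({"toL": y, "met5L": x}, index=idx), scale="log"
        )
        spec = sz.ModelSpec("toL", ("met5L",), mcmc=small_pmm_settings)
        fit = sz.fit_pmm(data, star_tree, spec, seed=63)
        beta_ols = np.linalg.lstsq(
            np.column_stack([np.ones(2 * n), x]), y, rcond=None
        )[0]
        sd = fit.draws_[["(Intercept)", "met5L"]].std()
        assert abs(fit.coef_["(Intercept)"] - beta_ols[0]) < 2 * sd["(Intercept)"]
        assert abs(fit.coef_["met5L"] - beta_ols[1]) < 2 * sd["met5L"]

    def test_sampler_matches_ml_oracle(self, tree80, data80, fit80):
        spec = sz.ModelSpec("toL", ("met5L",))
        ora = sz.fit_pgls_ml(data80, tree80, spec)
        for name in ["(Intercept)", "met5L"]:
            sd = fit80.draws_[name].std()
            assert abs(fit80.coef_[name] - ora.coef[name]) < 2 * sd


class TestPredictionsAndRMSE:
    def test_rmse_hand_arithmetic(self):
        model = PhylogeneticMixedModel.__new__(PhylogeneticMixedModel)
        model.fixed_names_ = ["(Intercept)", "met5L"]
        model.coef_ = pd.Series({"(Intercept)": 0.0, "met5L": 1.0})
        model.response = "toL"
        model.spec_ = sz.ModelSpec("toL", ("met5L",))
        idx = pd.MultiIndex.from_tuples(
            [("sp1", "female"), ("sp2", "female")], names=["species", "sex"]
        )
        # fixed-effect predictions exp(ln x) = {10, 8}; actual = {12, 8}
        frame = pd.DataFrame(
            {"toL": np.log([12.0, 8.0]), "met5L": np.log([10.0, 8.0])},
            index=idx,
        )
        data = sz.TraitMatrix(frame, scale="log")
        assert sz.rmse_mm(model, data) == pytest.approx(np.sqrt(2.0))

    def test_perfect_coefficients_give_zero_rmse(self, tree80):
        data = simulate_pmm_dataset(
            tree80, a=1.0, b=1.0, sigma2_phylo=0.0, sigma2_species=0.0,
            sigma2_resid=0.0, seed=64,
        )
        model = PhylogeneticMixedModel.__new__(PhylogeneticMixedModel)
        model.fixed_names_ = ["(Intercept)", "met5L"]
        model.coef_ = pd.Series({"(Intercept)": 1.0, "met5L": 1.0})
        model.response = "toL"
        model.spec_ = sz.ModelSpec("toL", ("met5L",))
        assert sz.rmse_mm(model, data) == pytest.approx(0.0, abs=1e-6)

    def test_sampler_near_zero_rmse_on_noiseless_data(self, tree80):
        data = simulate_pmm_dataset(
            tree80, a=1.0, b=1.0, sigma2_phylo=0.0, sigma2_species=0.0,
            sigma2_resid=1e-14, seed=64,
        )
        spec = sz.ModelSpec("toL", ("met5L",),
                            mcmc=sz.MCMCSettings(2000, 200, 5))
        fit = sz.fit_pmm(data, tree80, spec, seed=65)
        assert fit.rmse_ < 0.1  # mm, on ~10 mm scale measurements

    def test_predict_matches_equation(self, fit80, data80):
        pred = fit80.predict(data80)
        a = fit80.coef_["(Intercept)"]
        b = fit80.coef_["met5L"]
        manual = np.exp(a + b * data80.data["met5L"])
        np.testing.assert_allclose(pred.to_numpy(), manual.to_numpy())

    def test_coefficient_set_roundtrip(self, fit80):
        cs = fit80.coefficient_set()
        assert cs.source == "fitted"
        back = sz.CoefficientSet.from_json(cs.to_json())
        assert back == cs


class TestSexInteraction:
    def test_equal_slopes_not_significant(self, tree80, small_pmm_settings):
        hits = 0
        for rep in range(6):
            data = simulate_pmm_dataset(
                tree80, b=0.95, sex_slope_offset=0.0, seed=70 + rep
            )
            spec = sz.ModelSpec("toL", ("met5L",), mcmc=small_pmm_settings)
            res = sz.test_sex_interaction(data, tree80, spec, seed=80 + rep)
            hits += res["significant"]
        assert hits <= 1

    def test_slope_difference_detected(self, tree80, small_pmm_settings):
        hits = 0
        for rep in range(6):
            data = simulate_pmm_dataset(
                tree80, b=0.95, sex_slope_offset=0.3, seed=90 + rep
            )
            spec = sz.ModelSpec("toL", ("met5L",), mcmc=small_pmm_settings)
            res = sz.test_sex_interaction(data, tree80, spec, seed=100 + rep)
            hits += res["significant"]
        assert hits >= 5

    def test_intercept_only_dimorphism_not_significant(
        self, tree80, small_pmm_settings
    ):
        data = simulate_pmm_dataset(
            tree80, b=0.95, sex_offset=0.3, sex_slope_offset=0.0, seed=110
        )
        spec = sz.ModelSpec("toL", ("met5L",), mcmc=small_pmm_settings)
        res = sz.test_sex_interaction(data, tree80, spec, seed=111)
        assert not res["significant"]
        # the sex main effect itself is real and detected
        assert res["summary"].loc["sexmale", "pmcmc"] < 0.05

    def test_single_sex_rejected(self, tree80, small_pmm_settings):
        data = simulate_pmm_dataset(tree80, seed=112)
        females = sz.TraitMatrix(
            data.data[data.data.index.get_level_values("sex") == "female"],
            scale="log",
        )
        spec = sz.ModelSpec("toL", ("met5L",), mcmc=small_pmm_settings)
        with pytest.raises(ValueError, match="both sexes"):
            sz.test_sex_interaction(females, tree80, spec)


class TestModelSearch:
    def test_true_predictor_outranks_noise(self, tree80, small_pmm_settings):
        data = simulate_pmm_dataset(tree80, b=0.95, seed=120)
        rng = np.random.default_rng(121)
        frame = data.data.copy()
        frame["cheW"] = rng.normal(0.0, 0.3, size=len(frame))  # pure noise
        noisy = sz.TraitMatrix(frame, scale="log")
        table = sz.rank_predictors(
            noisy, tree80, "toL", ["met5L", "cheW"],
            mcmc=small_pmm_settings, seed=122,
        )
        assert table.loc[0, "predictor"] == "met5L"
        assert table.loc[0, "rmse_mm"] < table.loc[1, "rmse_mm"]

    def test_noise_secondary_does_not_improve_rmse(self, tree80,
                                                   small_pmm_settings):
        data = simulate_pmm_dataset(tree80, b=0.95, seed=130)
        rng = np.random.default_rng(131)
        frame = data.data.copy()
        frame["cheW"] = rng.normal(0.0, 0.3, size=len(frame))
        noisy = sz.TraitMatrix(frame, scale="log")
        single = sz.fit_pmm(
            noisy, tree80,
            sz.ModelSpec("toL", ("met5L",), mcmc=small_pmm_settings),
            seed=132,
        )
        double = sz.fit_two_predictor(
            noisy, tree80, "toL", "met5L", "cheW",
            mcmc=small_pmm_settings, seed=133,
        )
        assert double.rmse_ == pytest.approx(single.rmse_, rel=0.1)

    def test_duplicate_secondary_warns(self, tree80, small_pmm_settings):
        data = simulate_pmm_dataset(tree80, seed=134)
        frame = data.data.copy()
        frame["carL"] = frame["met5L"] + 1e-9  # numerically collinear copy
        dup = sz.TraitMatrix(frame, scale="log")
        with pytest.warns(UserWarning, match="collinear"):
            sz.fit_two_predictor(
                dup, tree80, "toL", "met5L", "carL",
                mcmc=small_pmm_settings, seed=135,
            )
        with pytest.raises(ValueError, match="differ"):
            sz.fit_two_predictor(dup, tree80, "toL", "met5L", "met5L")

    def test_constant_predictor_rejected(self, tree80, small_pmm_settings):
        data = simulate_pmm_dataset(tree80, seed=136)
        frame = data.data.copy()
        frame["teL"] = 1.0
        flat = sz.TraitMatrix(frame, scale="log")
        with pytest.raises(ValueError, match="constant"):
            sz.fit_pmm(
                flat, tree80,
                sz.ModelSpec("toL", ("teL",), mcmc=small_pmm_settings),
            )


class TestPriorSensitivity:
    def test_slope_robust_to_tenfold_nu(self, tree80, data80,
                                        small_pmm_settings):
        base = sz.fit_pmm(
            data80, tree80,
            sz.ModelSpec("toL", ("met5L",), mcmc=small_pmm_settings),
            seed=140,
        )
        alt = PhylogeneticMixedModel(
            tree80, response="toL", predictors=("met5L",),
            iterations=small_pmm_settings.iterations,
            burn_in=small_pmm_settings.burn_in,
            thin=small_pmm_settings.thin,
            prior_nu=0.02, random_state=141,
        ).fit(data80)
        assert alt.coef_["met5L"] == pytest.approx(
            base.coef_["met5L"], abs=2 * base.draws_["met5L"].std()
        )
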