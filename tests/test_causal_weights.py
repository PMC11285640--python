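"""Panel construction, stabilized-weight correctness, weighted MSM behavior."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mdd2ad import (
    SimulationConfig,
    fit_msm,
    predict_msm,
    rank_msm_features,
    simulate_population,
)
from mdd2ad.causal_weights import (
    ExposureModels,
    build_panel,
    compute_iptw,
    fit_exposure_models,
)
from mdd2ad.synthetic_claims import Claim, PatientRecord


def _patient(claims, pid="p1"):
    return PatientRecord(pid, "75-79", "female", "white", "rural", "partly",
                         sorted(claims, key=lambda c: c.year))


class TestBuildPanel:
    def test_eight_year_window_gives_eight_rows(self):
        rec = _patient([Claim(2012, "ICD9", "296.21", 3)])
        panel = build_panel([rec], 2012, 2019)
        assert len(panel) == 8
        assert panel["t"].tolist() == list(range(8))  # T = 7, t = 0..7

    def test_exposure_only_in_claim_years(self):
        rec = _patient([Claim(2012, "ICD9", "296.21", 3)])
        panel = build_panel([rec], 2012, 2019)
        assert panel["E"].tolist() == [1, 0, 0, 0, 0, 0, 0, 0]

    def test_time_varying_covariates_never_use_future_claims(self):
        base = [Claim(2012, "ICD9", "296.21", 3), Claim(2014, "ICD9", "401.9", 2)]
        perturbed = base + [Claim(2015, "ICD9", "296.22", 9)]
        p1 = build_panel([_patient(base)], 2012, 2019)
        p2 = build_panel([_patient(perturbed, pid="p1")], 2012, 2019)
        cols = ["E", "tv_comorbid", "tv_util", "tv_cum_mdd"]
        pd.testing.assert_frame_equal(
            p1[p1["t"] <= 2][cols].reset_index(drop=True),
            p2[p2["t"] <= 2][cols].reset_index(drop=True),
        )

    def test_cumulative_mdd_count_is_nondecreasing(self):
        rec = _patient(
            [Claim(2012, "ICD9", "296.21", 1), Claim(2013, "ICD9", "296.22", 1),
             Claim(2016, "ICD10", "F32.9", 1)]
        )
        panel = build_panel([rec], 2012, 2019)
        assert (np.diff(panel["tv_cum_mdd"]) >= 0).all()
        assert panel["tv_cum_mdd"].iloc[-1] == 3

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            build_panel([_patient([Claim(2012, "ICD9", "296.21", 1)])], 2015, 2014)


def _two_period_panel(Z0, E1):
    rows = []
    for i, (z, e) in enumerate(zip(Z0, E1)):
        pid = f"p{i:05d}"
        rows.append(dict(patient_id=pid, t=0, year=2000, E=1, tv_comorbid=int(z),
                         tv_util=0.0, tv_cum_mdd=1.0))
        rows.append(dict(patient_id=pid, t=1, year=2001, E=int(e), tv_comorbid=0,
                         tv_util=0.0, tv_cum_mdd=1.0))
    return pd.DataFrame(rows)


class TestStabilizedWeights:
    def test_saturated_panel_matches_direct_enumeration(self):
        # binary confounder, one informative lag: logistic fits are
        # saturated, so model weights must equal raw-frequency weights
        rng = np.random.default_rng(5)
        n = 400
        Z0 = rng.integers(0, 2, n)
        E1 = (rng.random(n) < np.where(Z0 == 1, 0.7, 0.3)).astype(int)
        panel = _two_period_panel(Z0, E1)
        weights = compute_iptw(panel, fit_exposure_models(panel))

        p_marg = E1.mean()
        p_cond = np.where(Z0 == 1, E1[Z0 == 1].mean(), E1[Z0 == 0].mean())
        num = np.where(E1 == 1, p_marg, 1 - p_marg)
        den = np.where(E1 == 1, p_cond, 1 - p_cond)
        oracle = num / den
        got = weights.sort_values("patient_id")["weight"].to_numpy()
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_weights_exactly_one_when_models_coincide(self):
        # time-varying columns carry no variation: numerator and
        # denominator designs are identical, so the products cancel
        rng = np.random.default_rng(6)
        E1 = rng.integers(0, 2, 300)
        panel = _two_period_panel(np.zeros(300, int), E1)
        weights = compute_iptw(panel, fit_exposure_models(panel))
        np.testing.assert_allclose(weights["weight"], 1.0, atol=1e-12)

    def test_hand_product_with_fixed_probabilities(self):
        # printed factor probabilities: (0.5*0.5)/(0.8*0.4) = 0.78125
        class Stub:
            def __init__(self, p):
                self.p, self.columns = p, []

            def predict(self, X):
                return np.full(len(X), self.p)

        panel = pd.DataFrame(
            [
                dict(patient_id="a", t=0, year=2000, E=1, tv_comorbid=0, tv_util=0.0, tv_cum_mdd=1.0),
                dict(patient_id="a", t=1, year=2001, E=1, tv_comorbid=0, tv_util=0.0, tv_cum_mdd=1.0),
                dict(patient_id="a", t=2, year=2002, E=1, tv_comorbid=0, tv_util=0.0, tv_cum_mdd=1.0),
            ]
        )
        models = ExposureModels(
            numerator_mode="covariate", per_year=True,
            num_fit={1: Stub(0.5), 2: Stub(0.5)},
            den_fit={1: Stub(0.8), 2: Stub(0.4)},
        )
        weights = compute_iptw(panel, models)
        assert weights["weight"].iloc[0] == pytest.approx(0.78125, abs=1e-12)

    def test_null_simulation_mean_weight_near_one(self):
        cfg = SimulationConfig(confounding_strength=0.0, seed=21)
        recs, _ = simulate_population(cfg, 3000)
        panel = build_panel(recs, cfg.start_year, cfg.end_year)
        weights = compute_iptw(panel, fit_exposure_models(panel))
        w = weights["weight"].to_numpy()
        assert abs(w.mean() - 1.0) < 3 * w.std() / np.sqrt(len(w))

    def test_confounding_inflates_weight_variance(self):
        null_cfg = SimulationConfig(confounding_strength=0.0, seed=22)
        conf_cfg = SimulationConfig(confounding_strength=2.0, seed=22)
        var = {}
        for name, cfg in [("null", null_cfg), ("conf", conf_cfg)]:
            recs, _ = simulate_population(cfg, 3000)
            panel = build_panel(recs, cfg.start_year, cfg.end_year)
            w = compute_iptw(panel, fit_exposure_models(panel))["weight"]
            var[name] = w.var()
        assert var["conf"] > var["null"]

    def test_weights_positive_and_finite(self, fitted_bundle):
        w = fitted_bundle["weights"]["weight"].to_numpy()
        assert np.all(w > 0) and np.all(np.isfinite(w))


class TestMsm:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=200), "b": rng.integers(0, 2, 200).astype(float)})
        y = (0.2 + 0.3 * X["a"] + 0.1 * X["b"] + rng.normal(0, 0.3, 200) > 0.4).astype(int)
        return X, y.to_numpy()

    def test_equal_weights_reduce_to_ols(self, toy):
        X, y = toy
        fit = fit_msm(X, y, np.full(len(y), 2.5))
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params.to_numpy(), atol=1e-10)

    def test_duplicated_rows_with_halved_weights_identical(self, toy):
        X, y = toy
        fit1 = fit_msm(X, y, np.ones(len(y)))
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = np.concatenate([y, y])
        fit2 = fit_msm(X2, y2, np.full(len(y2), 0.5))
        np.testing.assert_allclose(fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-10)

    def test_aliased_columns_dropped_with_warning(self, toy):
        X, y = toy
        X = X.assign(dup=X["a"] * 2.0)
        with pytest.warns(UserWarning, match="aliased"):
            fit = fit_msm(X, y, np.ones(len(y)))
        assert "dup" in fit.dropped or "a" in fit.dropped

    def test_nonpositive_weights_rejected(self, toy):
        X, y = toy
        with pytest.raises(ValueError):
            fit_msm(X, y, np.zeros(len(y)))

    def test_intercept_only_balanced_outcome_predicts_half(self):
        X = pd.DataFrame(index=range(10))
        y = np.array([0, 1] * 5)
        fit = fit_msm(X, y, np.ones(10))
        np.testing.assert_allclose(predict_msm(fit, X), 0.5, atol=1e-12)

    def test_predictions_clip_to_unit_interval(self, toy):
        X, y = toy
        fit = fit_msm(X, y, np.ones(len(y)))
        X_far = X * 50.0  # push the linear predictor outside [0, 1]
        p = predict_msm(fit, X_far)
        assert p.min() >= 0.0 and p.max() <= 1.0
        assert (p == 0.0).any() or (p == 1.0).any()

    def test_training_rows_reproduce_fitted_values(self, toy):
        X, y = toy
        fit = fit_msm(X, y, np.ones(len(y)))
        eta = sm.add_constant(X).to_numpy() @ fit.params.to_numpy()
        inside = (eta >= 0) & (eta <= 1)
        np.testing.assert_allclose(predict_msm(fit, X)[inside], eta[inside], atol=1e-10)

    def test_missing_design_column_rejected(self, toy):
        X, y = toy
        fit = fit_msm(X, y, np.ones(len(y)))
        with pytest.raises(ValueError, match="missing"):
            predict_msm(fit, X[["a"]])


class TestRankMsmFeatures:
    def _fit(self, coefs, pvals):
        return type(
            "F", (), {
                "columns": list(coefs),
                "params": pd.Series(coefs),
                "bse": pd.Series({k: 0.1 for k in coefs}),
                "pvalues": pd.Series(pvals),
            },
        )()

    def test_sorted_descending_by_coefficient(self):
        fit = self._fit({"a": 0.145, "b": 0.142, "c": 0.089}, {"a": 0.01, "b": 0.2, "c": 0.03})
        ranked = rank_msm_features(fit)
        assert ranked["feature"].tolist() == ["a", "b", "c"]
        assert ranked["significant"].tolist() == [True, False, True]

    def test_all_zero_ties_keep_input_order(self):
        fit = self._fit({"x": 0.0, "y": 0.0, "z": 0.0}, {"x": 1, "y": 1, "z": 1})
        assert rank_msm_features(fit)["feature"].tolist() == ["x", "y", "z"]

    def test_sign_flip_moves_rank(self):
        fit = self._fit({"a": 0.2, "b": 0.1}, {"a": 1, "b": 1})
        flipped = self._fit({"a": -0.2, "b": 0.1}, {"a": 1, "b": 1})
        assert rank_msm_features(fit)["feature"].tolist() == ["a", "b"]
        assert rank_msm_features(flipped)["feature"].tolist() == ["b", "a"]
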