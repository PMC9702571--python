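import numpy as np
import pandas as pd
import pytest

from ripdiv import (
    ModelRecord, SimulationConfig, aicc, akaike_weights, all_subsets_fit,
    average_top_set, fit_lmm_ml, simulate_driver_response, simulate_sites,
    stepwise_vif_filter, vif_scores,
)


def exactly_correlated_pair(n: int = 40, r: float = 0.6) -> pd.DataFrame:
    """Two columns whose sample correlation is exactly r, by construction."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    u = np.cos(t)                       # orthogonal, equal-norm pair
    v = np.sin(t)
    x1 = u
    x2 = r * u + np.sqrt(1 - r ** 2) * v
    return pd.DataFrame({"x1": x1, "x2": x2})


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        X = exactly_correlated_pair(r=0.0)
        assert np.allclose(vif_scores(X), 1.0, atol=1e-10)

    def test_exact_linear_combination_is_infinite(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x1", "x2"])
        X["x3"] = X["x1"] + X["x2"]
        assert np.isinf(vif_scores(X)["x3"])

    def test_closed_form_for_correlation_point_six(self):
        X = exactly_correlated_pair(r=0.6)
        v = vif_scores(X)
        assert v["x1"] == pytest.approx(1.5625, abs=1e-6)
        assert v["x2"] == pytest.approx(1.5625, abs=1e-6)

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"x1": np.arange(10.0), "x2": np.ones(10)})
        with pytest.raises(ValueError, match="constant"):
            vif_scores(X)


class TestStepwiseFilter:
    def test_low_vif_design_is_untouched(self):
        X = exactly_correlated_pair(r=0.3)
        kept, removed = stepwise_vif_filter(X, threshold=4)
        assert list(kept.columns) == ["x1", "x2"] and removed == []

    def test_duplicated_predictor_removed_once(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X["b"] = X["a"]
        X["c"] = rng.normal(size=30)
        kept, removed = stepwise_vif_filter(X, threshold=4)
        assert len(removed) == 1 and removed[0][0] in ("a", "b")
        assert kept.shape[1] == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_postcondition_no_retained_vif_above_threshold(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(40, 3))
        cols = {f"x{j}": base[:, j % 3] + 0.3 * rng.normal(size=40)
                for j in range(8)}
        kept, _ = stepwise_vif_filter(pd.DataFrame(cols), threshold=4)
        if kept.shape[1] >= 2:
            assert (vif_scores(kept) < 4).all()


class TestAicc:
    def test_hand_arithmetic(self):
        # -2(-10) + 2*3 + 2*3*4/(20 - 4) = 20 + 6 + 1.5
        assert aicc(-10.0, 3, 20) == pytest.approx(27.5, abs=1e-12)

    def test_equal_models_share_weight(self):
        w = akaike_weights(np.array([100.0, 100.0]))
        assert np.allclose(w, [0.5, 0.5], atol=1e-12)

    def test_delta_two_weight_ratio_is_exp_minus_one(self):
        w = akaike_weights(np.array([10.0, 12.0]))
        assert w[1] / w[0] == pytest.approx(np.exp(-1), abs=1e-12)

    def test_undefined_for_small_samples(self):
        with pytest.raises(ValueError):
            aicc(-5.0, 5, 6)


class TestLmm:
    def test_agrees_with_statsmodels_mixedlm(self):
        """Dual route: profiled-ML fitter vs statsmodels on one dataset."""
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(3)
        n, g = 60, 6
        groups = np.repeat(np.arange(g), n // g)
        x = rng.normal(size=n)
        y = 1.0 + 0.8 * x + rng.normal(0, 0.5, g)[groups] + rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        ours = fit_lmm_ml(y, X, groups)
        df = pd.DataFrame({"y": y, "x": x, "g": groups})
        theirs = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=False)
        assert ours["coef"] == pytest.approx(theirs.fe_params.to_numpy(), abs=1e-4)
        assert ours["loglik"] == pytest.approx(theirs.llf, abs=1e-3)
        assert ours["se"] == pytest.approx(theirs.bse_fe.to_numpy(), rel=0.05)

    def test_zero_group_variance_collapses_to_ols(self):
        rng = np.random.default_rng(4)
        n = 50
        groups = np.repeat(np.arange(5), 10)
        x = rng.normal(size=n)
        y = 2.0 - 0.5 * x + rng.normal(0, 1, n)   # no group effect
        X = np.column_stack([np.ones(n), x])
        fit = fit_lmm_ml(y, X, groups)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit["theta"] < 0.2
        assert fit["coef"] == pytest.approx(ols, abs=0.05)


@pytest.fixture(scope="module")
def sites():
    return simulate_sites(SimulationConfig(seed=2))


class TestAllSubsets:
    def test_two_predictors_give_four_models(self, sites):
        y = simulate_driver_response(sites, {"Forest": 0.5}, seed=0)
        X = sites.environment()[["Forest", "Lnum"]]
        recs = all_subsets_fit(y, X, sites)
        assert len(recs) == 4
        assert sum(abs(m.weight) for m in recs) == pytest.approx(1.0, abs=1e-12)
        assert recs[0].delta_aicc == 0.0

    def test_strong_single_driver_always_selected(self, sites):
        X = sites.environment()[["Forest", "Width"]]
        hits = 0
        for seed in range(50):
            y = simulate_driver_response(sites, {"Forest": 1.0},
                                         noise_sd=1.0, seed=seed)
            recs = all_subsets_fit(y, X, sites)
            hits += "Forest" in recs[0].predictors
        assert hits >= 48

    def test_intercept_only_truth_keeps_null_model_in_top_set(self, sites):
        X = sites.environment()[["Forest", "Width"]]
        hits = 0
        for seed in range(25):
            y = simulate_driver_response(sites, {}, noise_sd=1.0, seed=seed)
            recs = all_subsets_fit(y, X, sites)
            null = next(m for m in recs if m.predictors == ())
            hits += null.delta_aicc <= 2
        assert hits >= 20  # >= 80% of replicates

    def test_predictor_explosion_guard(self, sites):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(60, 16)),
                         index=sites.sites.index)
        X.columns = [f"x{i}" for i in range(16)]
        with pytest.raises(ValueError, match="guard"):
            all_subsets_fit(pd.Series(np.zeros(60), index=X.index), X, sites)


def toy_record(predictors, estimates, ses, loglik, kp, n=30):
    names = ["(Intercept)", *predictors]
    return ModelRecord(tuple(predictors), dict(zip(names, estimates)),
                       dict(zip(names, ses)), loglik, kp,
                       aicc(loglik, kp, n))


def finalize(records):
    a = np.array([m.aicc for m in records])
    w = akaike_weights(a)
    for m, wi in zip(records, w):
        m.delta_aicc = m.aicc - a.min()
        m.weight = float(wi)
    return sorted(records, key=lambda m: m.aicc)


class TestAveraging:
    def test_single_model_passes_through(self):
        recs = finalize([toy_record(["x1"], [0.5, 0.8], [0.1, 0.2], -10, 4)])
        avg = average_top_set(recs)
        assert avg.table.loc["x1", "Estimate"] == pytest.approx(0.8)
        assert avg.table.loc["x1", "importance"] == pytest.approx(1.0)

    def test_zero_substitution_halves_estimate_for_equal_weights(self):
        recs = finalize([
            toy_record(["x1"], [0.0, 0.8], [0.1, 0.2], -10, 4),
            toy_record([], [0.0], [0.1], -12, 3),  # tuned below to equal AICc
        ])
        # force exactly equal weights by assigning equal AICc
        for m in recs:
            m.aicc = 20.0
        recs = finalize(recs)
        avg = average_top_set(recs)
        assert avg.table.loc["x1", "Estimate"] == pytest.approx(0.4)
        assert avg.table.loc["x1", "importance"] == pytest.approx(0.5)

    def test_three_model_hand_oracle(self):
        """Averaged estimates equal an independently hand-computed weighted sum."""
        recs = finalize([
            toy_record(["x1"], [0.1, 1.0], [0.1, 0.2], -10.0, 4),
            toy_record(["x1", "x2"], [0.2, 0.8, 0.3], [0.1, 0.25, 0.15], -9.5, 5),
            toy_record(["x2"], [0.0, 0.5], [0.1, 0.2], -10.4, 4),
        ])
        avg = average_top_set(recs, delta=np.inf)
        a = np.array([m.aicc for m in recs])
        w = np.exp(-(a - a.min()) / 2)
        w = w / w.sum()
        est = {m.predictors: m.estimates for m in recs}
        x1_hand = sum(wi * est[p].get("x1", 0.0) for wi, p in
                      zip(w, [m.predictors for m in recs]))
        x2_hand = sum(wi * est[p].get("x2", 0.0) for wi, p in
                      zip(w, [m.predictors for m in recs]))
        assert avg.table.loc["x1", "Estimate"] == pytest.approx(x1_hand, abs=1e-10)
        assert avg.table.loc["x2", "Estimate"] == pytest.approx(x2_hand, abs=1e-10)
        # importance: summed weight of the models containing the predictor
        imp_hand = sum(wi for wi, m in zip(w, recs) if "x1" in m.predictors)
        assert avg.table.loc["x1", "importance"] == pytest.approx(imp_hand, abs=1e-10)

    def test_order_invariance(self):
        recs = finalize([
            toy_record(["x1"], [0.1, 1.0], [0.1, 0.2], -10.0, 4),
            toy_record(["x2"], [0.0, 0.5], [0.1, 0.2], -10.4, 4),
        ])
        a = average_top_set(recs, delta=np.inf).table
        b = average_top_set(list(reversed(recs)), delta=np.inf).table
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_conditional_averaging_skips_zero_substitution(self):
        recs = finalize([
            toy_record(["x1"], [0.0, 0.8], [0.1, 0.2], -10, 4),
            toy_record([], [0.0], [0.1], -10, 3),
        ])
        for m in recs:
            m.aicc = 20.0
        recs = finalize(recs)
        avg = average_top_set(recs, conditional=True)
        assert avg.table.loc["x1", "Estimate"] == pytest.approx(0.8)
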