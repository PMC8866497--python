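"""Cox fitting, propensity scores, weights, matching, and the estimators."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import norm

import textconfound as tc

# 4 subjects, distinct event times, binary covariate
TOY_DURATIONS = np.array([5.0, 8.0, 11.0, 16.0])
TOY_EVENTS = np.array([1, 1, 1, 1])
TOY_X = np.array([1.0, 0.0, 1.0, 0.0])


def breslow_partial_loglik(b: float, x, t, e) -> float:
    """Hand-written Cox partial log-likelihood (no ties)."""
    ll = 0.0
    for i in range(len(t)):
        if e[i]:
            risk = [j for j in range(len(t)) if t[j] >= t[i]]
            ll += b * x[i] - np.log(sum(np.exp(b * x[j]) for j in risk))
    return ll


class TestFitCox:
    def test_matches_bruteforce_partial_likelihood(self):
        model = tc.fit_cox(
            pd.DataFrame({"x": TOY_X}), None, (TOY_DURATIONS, TOY_EVENTS)
        )
        res = minimize_scalar(
            lambda b: -breslow_partial_loglik(b, TOY_X, TOY_DURATIONS, TOY_EVENTS),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert abs(model.coefficients["x"] - res.x) < 1e-6

    def test_zero_effect_covariate_gives_hr_one(self):
        # covariate orthogonal to the risk ordering by symmetry
        x = np.array([1.0, 0.0, 0.0, 1.0, 1.0, 0.0])
        t = np.array([3.0, 4.0, 7.0, 8.0, 12.0, 13.0])
        e = np.ones(6, int)
        model = tc.fit_cox(pd.DataFrame({"x": x}), None, (t, e))
        res = minimize_scalar(
            lambda b: -breslow_partial_loglik(b, x, t, e),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-10},
        )
        assert abs(model.coefficients["x"] - res.x) < 1e-6

    def test_wald_p_matches_closed_form(self):
        model = tc.fit_cox(
            pd.DataFrame({"x": TOY_X}), None, (TOY_DURATIONS, TOY_EVENTS)
        )
        z = model.coefficients["x"] / model.se["x"]
        assert abs(model.p_values["x"] - 2 * norm.sf(abs(z))) < 1e-10

    def test_uniformly_rescaled_weights_leave_estimate_unchanged(self):
        rng = np.random.default_rng(4)
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        e = np.ones(n, int)
        w = rng.uniform(0.5, 2.0, n)
        m1 = tc.fit_cox(pd.DataFrame({"x": x}), None, (t, e), weights=w)
        m2 = tc.fit_cox(pd.DataFrame({"x": x}), None, (t, e), weights=2 * w)
        assert abs(m1.coefficients["x"] - m2.coefficients["x"]) < 1e-8

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            tc.fit_cox(None, np.array([0, 1]), (np.array([1.0, 2.0]), np.array([0, 0])))


class TestEstimatePropensity:
    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        n = 2000
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        W = (rng.random(n) < 0.4).astype(int)
        fit = tc.estimate_propensity(X, W, "logistic", seed=0)
        se = np.sqrt(W.mean() * (1 - W.mean()) / n)
        assert abs(fit.scores.mean() - W.mean()) < 3 * se

    def test_logistic_recovers_true_scores(self):
        cfg = tc.SimulationConfig(n_patients=5000, seed=21)
        _, manifest = tc.generate_cohort(cfg)
        design = pd.DataFrame(
            {
                "age": (manifest.structured["age"] - 68.0) / 8.0,
                "stage": manifest.structured["clinical_stage_true"] - 2.0,
            }
        )
        for k, name in enumerate(manifest.confounder_names):
            design[name] = manifest.term_indicators[:, k]
        fit = tc.estimate_propensity(design, manifest.W, "logistic", seed=0)
        rmse = np.sqrt(np.mean((fit.scores - manifest.true_propensity) ** 2))
        assert rmse < 0.05

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(300, 2)), columns=["a", "b"])
        W = (rng.random(300) < 0.5).astype(int)
        for learner in tc.survival.PROPENSITY_LEARNERS:
            f1 = tc.estimate_propensity(X, W, learner, seed=3)
            f2 = tc.estimate_propensity(X, W, learner, seed=3)
            np.testing.assert_array_equal(f1.scores, f2.scores)

    def test_unknown_learner_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="unknown learner"):
            tc.estimate_propensity(X, np.array([0, 1, 0, 1]), "svm")

    def test_single_arm_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0]})
        with pytest.raises(ValueError, match="arms"):
            tc.estimate_propensity(X, np.array([1, 1]), "logistic")


def _fake_fit(learner, smds, clip=0.0):
    n = len(smds)
    return tc.PropensityFit(
        learner=learner,
        scores=np.full(10, 0.5),
        balance=pd.DataFrame(
            {"smd_before": np.ones(n), "smd_after": np.array(smds)}
        ),
        overlap={"clip_fraction_treated": clip, "clip_fraction_control": clip},
    )


class TestSelectPropensityModel:
    def test_singleton(self):
        fit = _fake_fit("logistic", [0.1])
        assert tc.select_propensity_model([fit]) is fit

    def test_better_balance_wins(self):
        a = _fake_fit("gradient_boosting", [0.02, 0.04])
        b = _fake_fit("logistic", [0.10, 0.12])
        assert tc.select_propensity_model([a, b]) is a

    def test_tie_prefers_logistic(self):
        a = _fake_fit("random_forest", [0.05])
        b = _fake_fit("logistic", [0.05])
        assert tc.select_propensity_model([a, b]) is b

    def test_overlap_failure_rejected(self):
        bad = _fake_fit("logistic", [0.01], clip=0.2)
        with pytest.raises(ValueError, match="overlap"):
            tc.select_propensity_model([bad])


class TestStabilizedWeights:
    @pytest.mark.parametrize(
        "w, e, expected",
        [(1, 0.3, 1.0), (1, 0.9, 1.0), (0, 0.5, 1.0), (0, 0.8, 4.0), (0, 0.2, 0.25)],
    )
    def test_formula(self, w, e, expected):
        got = tc.stabilized_weights(np.array([e]), np.array([w]))
        np.testing.assert_allclose(got, [expected], atol=1e-12)

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            tc.stabilized_weights(np.array([0.0]), np.array([0]))
        with pytest.raises(ValueError):
            tc.stabilized_weights(np.array([1.0]), np.array([1]))


def greedy_match_oracle(scores, W):
    """Independent re-implementation: descending treated, nearest control."""
    treated = sorted(
        [i for i in range(len(W)) if W[i] == 1], key=lambda i: (-scores[i], i)
    )
    available = [i for i in range(len(W)) if W[i] == 0]
    pairs = []
    for t in treated:
        if not available:
            break
        best = min(available, key=lambda c: (abs(scores[c] - scores[t]), available.index(c)))
        available.remove(best)
        pairs.append((t, best))
    return pairs


class TestNNMMatch:
    def test_nearest_pair(self):
        scores = np.array([0.8, 0.7, 0.2])
        W = np.array([1, 0, 0])
        assert tc.nnm_match(scores, W) == [(0, 1)]

    def test_without_replacement_count(self):
        scores = np.array([0.6, 0.5, 0.4, 0.45, 0.55])
        W = np.array([1, 1, 1, 0, 0])
        pairs = tc.nnm_match(scores, W)
        assert len(pairs) == 2
        controls = [c for _, c in pairs]
        assert len(set(controls)) == len(controls)

    def test_matches_oracle_on_all_arm_splits(self):
        scores = np.array([0.81, 0.62, 0.44, 0.29, 0.74, 0.55, 0.38, 0.21])
        for treated_idx in itertools.combinations(range(8), 4):
            W = np.zeros(8, int)
            W[list(treated_idx)] = 1
            assert tc.nnm_match(scores, W) == greedy_match_oracle(scores, W)


def _confounded_toy(n=600, seed=14, b_w=0.0):
    # treated fraction kept below 1/3 so matching has a rich control pool
    rng = np.random.default_rng(seed)
    z = (rng.random(n) < 0.4).astype(float)
    e = 1 / (1 + np.exp(-(1.2 * z - 1.5)))
    W = (rng.random(n) < e).astype(int)
    lam = 0.001 * np.exp(1.0 * z + b_w * W)
    t = np.ceil(rng.exponential(1 / lam))
    return pd.DataFrame({"z": z}), W, (t, np.ones(n, int))


class TestEstimators:
    def test_iptw_with_constant_half_scores_equals_unweighted(self):
        _, W, outcome = _confounded_toy()
        fit = tc.PropensityFit(
            learner="logistic",
            scores=np.full(len(W), 0.5),
            balance=pd.DataFrame({"smd_before": [0.0], "smd_after": [0.0]}),
            overlap={"clip_fraction_treated": 0, "clip_fraction_control": 0},
        )
        est = tc.hr_iptw(outcome, W, fit)
        unweighted = tc.fit_cox(None, W, outcome)
        assert abs(est.log_hr - unweighted.coefficients["W"]) < 1e-10

    def test_multicoxph_reduces_to_univariate(self):
        _, W, outcome = _confounded_toy()
        est, _ = tc.hr_multicoxph(outcome, W, None, pd.DataFrame(index=range(len(W))))
        uni = tc.fit_cox(None, W, outcome)
        assert abs(est.log_hr - uni.coefficients["W"]) < 1e-10

    def test_adjustment_reduces_confounding_bias(self):
        X, W, outcome = _confounded_toy(n=2000, seed=3)
        fit = tc.estimate_propensity(X, W, "logistic", seed=0)
        unadj = tc.fit_cox(None, W, outcome).coefficients["W"]
        for est in [
            tc.hr_iptw(outcome, W, fit),
            tc.hr_matching(outcome, W, fit),
            tc.hr_multicoxph(outcome, W, fit, X)[0],
        ]:
            assert abs(est.log_hr) < abs(unadj)

    def test_collinear_design_rejected(self):
        X, W, outcome = _confounded_toy()
        X2 = X.copy()
        X2["z_dup"] = X["z"]
        with pytest.raises(ValueError, match="z_dup"):
            tc.hr_multicoxph(outcome, W, None, X2)


class TestCovariateHRTable:
    def test_row_count_and_wald_p(self):
        rng = np.random.default_rng(17)
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        W = (rng.random(n) < 0.5).astype(int)
        t = np.ceil(rng.exponential(1000 * np.exp(-0.5 * X["a"].to_numpy())))
        outcome = (t, np.ones(n, int))
        table = tc.covariate_hr_table(X, W, outcome, intersection=["b"])
        assert len(table) == 4  # treatment row + 3 covariates
        assert table.iloc[0]["covariate"] == "W"
        assert "b*" in set(table["covariate"])
        # univariate Wald p recomputed from the reported HR/CI
        for _, row in table.iterrows():
            log_hr = np.log(row["uni_hr"])
            se = (np.log(row["uni_ci_high"]) - np.log(row["uni_ci_low"])) / (
                2 * norm.ppf(0.975)
            )
            assert abs(row["uni_p"] - 2 * norm.sf(abs(log_hr / se))) < 1e-10
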