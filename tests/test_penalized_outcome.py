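import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.linear_model import ElasticNet

from hetefx import (
    CohortTable,
    DesignSpec,
    FittedOutcomeModel,
    PenaltySpec,
    VariableRoles,
    build_design,
    fit_iptw,
    fit_penalized,
    penalty_loss,
    post_double_select,
    standardize,
)
from hetefx.penalized_outcome import _cd_gaussian, _fit_binomial


def _gaussian_problem(n=400, p=6, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.array([1.5, -2.0, 0.0, 0.0, 0.5, 0.0])
    y = X @ beta + rng.standard_normal(n)
    return X, y


class TestPenaltyLoss:
    def test_lambda_zero_is_rss(self):
        X, y = _gaussian_problem()
        beta = np.full(X.shape[1], 0.3)
        rss = float(np.sum((y - X @ beta) ** 2))
        assert penalty_loss(y, X, beta, lam=0.0, alpha=0.7) == pytest.approx(rss, abs=1e-10)

    def test_lasso_penalty_hand_arithmetic(self):
        X = np.eye(2)
        y = np.zeros(2)
        beta = np.array([1.0, -2.0])
        sse = float(np.sum((y - X @ beta) ** 2))
        # alpha=1, lambda=3: penalty is 3*(|1|+|-2|) = 9 on top of the SSE
        assert penalty_loss(y, X, beta, lam=3.0, alpha=1.0) == pytest.approx(sse + 9.0)

    def test_zero_everything(self):
        X = np.ones((2, 1))
        assert penalty_loss(np.zeros(2), X, np.zeros(1), lam=5.0, alpha=1.0) == 0.0

    def test_elastic_net_mixing(self):
        X = np.eye(2)
        beta = np.array([2.0, 0.0])
        lam, alpha = 4.0, 0.25
        sse = 4.0  # (0 - 2)^2 + 0
        penalty = lam * (alpha * abs(2.0) + (1 - alpha) / 2 * 2.0**2)
        got = penalty_loss(np.zeros(2), X, beta, lam=lam, alpha=alpha)
        assert got == pytest.approx(sse + penalty)

    def test_invalid_parameters(self):
        X, y = np.eye(2), np.zeros(2)
        with pytest.raises(ValueError):
            penalty_loss(y, X, np.zeros(2), lam=-1.0, alpha=1.0)
        with pytest.raises(ValueError):
            penalty_loss(y, X, np.zeros(2), lam=1.0, alpha=1.5)


class TestSolverOracles:
    def test_lambda_zero_matches_ols(self):
        X, y = _gaussian_problem()
        b0, beta = _cd_gaussian(X, y, 0.0, 1.0, np.ones(X.shape[1]), np.zeros(X.shape[1]), 0.0)
        ols = sm.OLS(y, sm.add_constant(X)).fit().params
        np.testing.assert_allclose(np.r_[b0, beta], ols, atol=1e-6)

    def test_lambda_zero_matches_logistic_glm(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 4))
        eta = 0.4 + X @ np.array([1.0, -0.8, 0.0, 0.3])
        y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(float)
        b0, beta = _fit_binomial(X, y, 0.0, 1.0, np.ones(4), np.zeros(4), 0.0)
        glm = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit().params
        np.testing.assert_allclose(np.r_[b0, beta], glm, atol=1e-6)

    @pytest.mark.parametrize("a_sk,l1", [(0.05, 1.0), (0.02, 0.5), (0.1, 0.2)])
    def test_matches_sklearn_elastic_net(self, a_sk, l1):
        # objective scale identity: lambda = 2n * alpha_sklearn, alpha = l1_ratio
        X, y = _gaussian_problem()
        n = len(y)
        b0, beta = _cd_gaussian(X, y, 2 * n * a_sk, l1, np.ones(X.shape[1]),
                                np.zeros(X.shape[1]), 0.0)
        sk = ElasticNet(alpha=a_sk, l1_ratio=l1, tol=1e-10, max_iter=200_000).fit(X, y)
        np.testing.assert_allclose(beta, sk.coef_, atol=1e-7)
        assert b0 == pytest.approx(sk.intercept_, abs=1e-7)

    def test_ridge_limit_alpha_near_zero(self):
        X, y = _gaussian_problem()
        p = X.shape[1]
        lam = 50.0
        _, beta = _cd_gaussian(X, y, lam, 1e-6, np.ones(p), np.zeros(p), 0.0)
        Xc, yc = X - X.mean(0), y - y.mean()
        closed = np.linalg.solve(2 * Xc.T @ Xc + lam * np.eye(p), 2 * Xc.T @ yc)
        np.testing.assert_allclose(beta, closed, atol=1e-4)

    def test_huge_lambda_zeroes_everything(self):
        X, y = _gaussian_problem()
        b0, beta = _cd_gaussian(X, y, 1e9, 1.0, np.ones(X.shape[1]), np.zeros(X.shape[1]), 0.0)
        assert np.all(beta == 0.0)
        assert b0 == pytest.approx(y.mean(), abs=1e-10)


def _sim_design(n, seed, beta_treat=0.0, beta_int=None, noise=1.0):
    """Small cohort + standardized order-1 design with known coefficients."""
    rng = np.random.default_rng(seed)
    p = 4
    C = rng.standard_normal((n, p))
    x = rng.integers(0, 2, n).astype(float)
    beta_int = np.zeros(p) if beta_int is None else beta_int
    y = 0.2 + beta_treat * x + C @ np.array([0.4, 0.0, 0.0, 0.0]) \
        + (x[:, None] * C) @ beta_int + noise * rng.standard_normal(n)
    df = pd.DataFrame(C, columns=[f"c{i}" for i in range(1, p + 1)])
    df.insert(0, "y", y)
    df.insert(0, "treatment", x)
    t = CohortTable(df)
    covs = [f"c{i}" for i in range(1, p + 1)]
    design = standardize(build_design(t, VariableRoles(covs, covs), DesignSpec()))
    return t, design, y


class TestFitPenalized:
    def test_cv_determinism(self):
        _, design, y = _sim_design(300, seed=5)
        spec = PenaltySpec(alpha=1.0, lam="cv", n_folds=5, fold_seed=9)
        a = fit_penalized(design, y, spec)
        b = fit_penalized(design, y, spec)
        assert a.lam == b.lam
        np.testing.assert_array_equal(a.cv_lambdas, b.cv_lambdas)
        pd.testing.assert_series_equal(a.coef, b.coef)

    def test_pure_noise_interactions_controlled(self):
        """All-null treatment interactions: the 1-SE rule zeroes them in
        >=90% of seeds; the CV-minimum rule may retain a few with tiny
        coefficients (sklearn's LassoCV behaves the same way)."""
        zeroed_1se, max_coef_min = 0, 0.0
        for s in range(10):
            _, design, y = _sim_design(2000, seed=s, beta_treat=0.3)
            ints = [c for c in design.columns if c.startswith("treatment*")]
            fit_1se = fit_penalized(design, y, PenaltySpec(lam="cv", fold_seed=s, one_se=True))
            zeroed_1se += all(fit_1se.coef[c] == 0.0 for c in ints)
            fit_min = fit_penalized(design, y, PenaltySpec(lam="cv", fold_seed=s))
            max_coef_min = max(max_coef_min, max(abs(fit_min.coef[c]) for c in ints))
        assert zeroed_1se >= 9
        assert max_coef_min < 0.1

    def test_strong_predictor_recovered(self):
        rng = np.random.default_rng(3)
        n = 2000
        C = rng.standard_normal((n, 5))
        y = 2.0 * C[:, 0] + rng.standard_normal(n)
        df = pd.DataFrame(C, columns=[f"c{i}" for i in range(1, 6)])
        df.insert(0, "y", y)
        df.insert(0, "treatment", rng.integers(0, 2, n).astype(float))
        t = CohortTable(df)
        covs = [f"c{i}" for i in range(1, 6)]
        design = standardize(build_design(t, VariableRoles(covs, []), DesignSpec()))
        fit = fit_penalized(design, y, PenaltySpec(lam="cv", fold_seed=3))
        assert fit.coef["c1"] == pytest.approx(2.0, abs=0.2)

    def test_treatment_main_never_penalized(self):
        _, design, y = _sim_design(500, seed=7, beta_treat=0.5)
        fit = fit_penalized(design, y, PenaltySpec(lam=1e7))
        assert all(fit.coef[c] == 0.0 for c in design.columns if c != "treatment")
        assert fit.coef["treatment"] != 0.0

    def test_binomial_family_validation(self):
        _, design, y = _sim_design(200, seed=0)
        with pytest.raises(ValueError, match="0/1"):
            fit_penalized(design, y, PenaltySpec(family="binomial"))

    def test_json_round_trip(self):
        _, design, y = _sim_design(200, seed=0)
        fit = fit_penalized(design, y, PenaltySpec(lam=10.0))
        back = FittedOutcomeModel.from_json(fit.to_json())
        pd.testing.assert_series_equal(back.coef, fit.coef)
        assert back.intercept == fit.intercept


class TestPostDoubleSelect:
    def test_instrument_kept_via_propensity_branch(self):
        # c1 drives treatment only; the propensity branch must retain it
        rng = np.random.default_rng(2)
        n = 3000
        C = rng.standard_normal((n, 3))
        x = (rng.random(n) < 1 / (1 + np.exp(-(1.5 * C[:, 0])))).astype(float)
        y = 0.5 * x + 0.8 * C[:, 1] + rng.standard_normal(n)
        df = pd.DataFrame(C, columns=["c1", "c2", "c3"])
        df.insert(0, "y", y)
        df.insert(0, "treatment", x)
        t = CohortTable(df)
        roles = VariableRoles(["c1", "c2", "c3"], ["c1", "c2", "c3"])
        design = standardize(build_design(t, roles, DesignSpec()))
        terms = post_double_select(t, roles, PenaltySpec(lam="cv", fold_seed=0), design)
        assert "c1" in terms  # instrument-like covariate
        assert "c2" in terms  # outcome predictor
        assert "treatment" in terms

    def test_pure_noise_covariate_mostly_excluded(self):
        kept = 0
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            n = 5000
            C = rng.standard_normal((n, 2))
            x = rng.integers(0, 2, n).astype(float)
            y = 0.3 * x + 0.8 * C[:, 0] + rng.standard_normal(n)
            df = pd.DataFrame(C, columns=["signal", "noise"])
            df.insert(0, "y", y)
            df.insert(0, "treatment", x)
            t = CohortTable(df)
            roles = VariableRoles(["signal", "noise"], ["signal", "noise"])
            design = standardize(build_design(t, roles, DesignSpec()))
            terms = post_double_select(
                t, roles, PenaltySpec(lam="cv", fold_seed=s, one_se=True), design)
            kept += "noise" in terms
        assert kept <= 1


class TestIptw:
    def test_randomized_treatment_weights_near_one(self):
        rng = np.random.default_rng(0)
        n = 5000
        df = pd.DataFrame({
            "treatment": rng.integers(0, 2, n).astype(float),
            "y": rng.random(n),
            "c1": rng.standard_normal(n),
            "c2": rng.standard_normal(n),
        })
        wv = fit_iptw(CohortTable(df), ["c1", "c2"])
        assert np.max(np.abs(wv.weights - 1.0)) < 0.15
        assert wv.weights.mean() == pytest.approx(1.0, abs=0.05)

    def test_confounded_cohort_balances_after_weighting(self, a1_sim):
        wv = fit_iptw(a1_sim.table, ["age", "sbp", "sex"])
        assert (wv.balance["smd_unweighted"].abs() > 0.1).any()  # IPTW has work to do
        assert (wv.balance["smd_weighted"].abs() < 0.1).all()
        assert wv.weights.mean() == pytest.approx(1.0, abs=0.1)

    def test_perfect_separation_detected(self):
        df = pd.DataFrame({
            "treatment": [0.0] * 10 + [1.0] * 10,
            "y": np.linspace(0, 1, 20),
            "c": np.r_[np.zeros(10), np.ones(10)],
        })
        with pytest.raises(ValueError, match="separation|positivity"):
            fit_iptw(CohortTable(df), ["c"])
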