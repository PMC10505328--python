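"""Elastic-net solver contracts, lambda-path CV, and the replicated
derivation protocol."""

import numpy as np
import pandas as pd
import pytest

from hlmetsig import DimensionError, ValidationError
from hlmetsig.signature import (
    CVResult, ElasticNetSpec, cv_lambda_path, derive_signature,
    elastic_net_objective, fit_elastic_net, lambda_max, score_signature,
    select_alpha,
)


def _standardized(rng, n, p):
    X = rng.normal(size=(n, p))
    return (X - X.mean(0)) / X.std(0)


class TestObjectiveAndSolver:
    def test_objective_at_zero_is_half_variance(self):
        rng = np.random.default_rng(0)
        X = _standardized(rng, 50, 3)
        y = rng.normal(size=50)
        y -= y.mean()
        spec = ElasticNetSpec(alpha=0.5, lam=0.7)
        got = elastic_net_objective(0.0, np.zeros(3), X, y, spec)
        assert got == pytest.approx(0.5 * np.var(y))

    def test_one_dim_lasso_matches_soft_threshold(self):
        rng = np.random.default_rng(1)
        x = _standardized(rng, 300, 1)
        y = 0.8 * x[:, 0] + rng.normal(scale=0.3, size=300)
        c = float(x[:, 0] @ (y - y.mean())) / 300
        for lam in (0.1, 0.5, abs(c) + 0.1):
            _, b = fit_elastic_net(
                x, y, ElasticNetSpec(alpha=1.0, lam=lam, standardize=False))
            soft = np.sign(c) * max(abs(c) - lam, 0.0)
            assert b[0] == pytest.approx(soft, abs=1e-6)

    def test_ridge_matches_closed_form(self):
        rng = np.random.default_rng(2)
        X = _standardized(rng, 200, 3)
        y = X @ [1.0, -0.5, 0.0] + rng.normal(scale=0.4, size=200)
        lam = 0.25
        _, b = fit_elastic_net(
            X, y, ElasticNetSpec(alpha=0.0, lam=lam, standardize=False))
        closed = np.linalg.solve(X.T @ X + 200 * lam * np.eye(3),
                                 X.T @ (y - y.mean()))
        np.testing.assert_allclose(b, closed, atol=1e-6)

    def test_zero_lambda_matches_ols(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(150, 4))
        y = X @ [1.0, 2.0, -1.0, 0.5] + rng.normal(size=150)
        b0, b = fit_elastic_net(X, y, ElasticNetSpec(alpha=0.3, lam=0.0))
        sol = np.linalg.lstsq(np.column_stack([np.ones(150), X]), y, rcond=None)[0]
        assert b0 == pytest.approx(sol[0], abs=1e-6)
        np.testing.assert_allclose(b, sol[1:], atol=1e-6)

    def test_full_shrinkage_leaves_intercept_only(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 5))
        y = rng.normal(loc=3.0, size=100)
        b0, b = fit_elastic_net(X, y, ElasticNetSpec(alpha=0.5, lam=1e3))
        np.testing.assert_array_equal(b, 0.0)
        assert b0 == pytest.approx(y.mean())
        # logistic analogue: intercept = logit of prevalence
        yb = (rng.random(100) < 0.3).astype(float)
        b0l, bl = fit_elastic_net(
            X, yb, ElasticNetSpec(family="logistic", alpha=0.5, lam=1e3))
        np.testing.assert_allclose(bl, 0.0, atol=1e-8)
        prev = yb.mean()
        assert b0l == pytest.approx(np.log(prev / (1 - prev)), abs=0.05)

    def test_solution_beats_random_perturbations(self):
        rng = np.random.default_rng(5)
        X = _standardized(rng, 120, 6)
        y = X @ [1, 0, 0, -1, 0, 0.5] + rng.normal(scale=0.5, size=120)
        spec = ElasticNetSpec(alpha=0.5, lam=0.05, standardize=False)
        b0, b = fit_elastic_net(X, y, spec)
        f0 = elastic_net_objective(b0, b, X, y, spec)
        for _ in range(1000):
            db = rng.normal(scale=0.02, size=6)
            assert f0 <= elastic_net_objective(b0, b + db, X, y, spec) + 1e-10

    def test_nonfinite_input_raises(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            fit_elastic_net(X, np.ones(10), ElasticNetSpec())


class TestLambdaPath:
    def test_all_zero_at_lambda_max(self):
        rng = np.random.default_rng(6)
        X = _standardized(rng, 200, 8)
        y = X @ ([0.5] * 8) + rng.normal(size=200)
        lmax = lambda_max(X, y, alpha=0.5)
        _, b = fit_elastic_net(
            X, y, ElasticNetSpec(alpha=0.5, lam=lmax, standardize=False))
        np.testing.assert_allclose(b, 0.0, atol=1e-10)
        _, b2 = fit_elastic_net(
            X, y, ElasticNetSpec(alpha=0.5, lam=0.5 * lmax, standardize=False))
        assert np.any(b2 != 0)

    def test_lambda_1se_at_least_lambda_min(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(150, 10))
        y = X[:, 0] - X[:, 1] + rng.normal(scale=0.8, size=150)
        for seed in (0, 1, 2):
            cv = cv_lambda_path(X, y, alpha=0.5, K=5, seed=seed)
            assert cv.lambda_1se >= cv.lambda_min
            assert cv.lambda_1se in cv.lambda_path

    def test_strong_signal_retains_predictors_at_1se(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 20))
        y = X @ np.r_[2.0, -2.0, np.zeros(18)] + rng.normal(scale=0.5, size=300)
        cv = cv_lambda_path(X, y, alpha=0.5, K=10, seed=1)
        _, b = fit_elastic_net(X, y, ElasticNetSpec(alpha=0.5, lam=cv.lambda_1se))
        assert np.count_nonzero(b) >= 1

    def test_support_at_1se_no_larger_than_at_min(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 30))
        y = X @ np.r_[1.0, -1.0, 0.5, np.zeros(27)] + rng.normal(size=200)
        cv = cv_lambda_path(X, y, alpha=0.5, K=10, seed=3)
        _, b_min = fit_elastic_net(X, y, ElasticNetSpec(alpha=0.5, lam=cv.lambda_min))
        _, b_1se = fit_elastic_net(X, y, ElasticNetSpec(alpha=0.5, lam=cv.lambda_1se))
        assert np.count_nonzero(b_1se) <= np.count_nonzero(b_min)

    def test_constant_response_raises(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        with pytest.raises(ValidationError):
            cv_lambda_path(X, np.ones(50), alpha=0.5, K=5, seed=0)

    def test_logistic_path_runs_and_orders(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(150, 5))
        y = (X[:, 0] + rng.normal(size=150) > 0).astype(float)
        cv = cv_lambda_path(X, y, family="logistic", alpha=0.5, K=4, seed=0,
                            n_lambda=30)
        assert isinstance(cv, CVResult)
        assert cv.lambda_1se >= cv.lambda_min


class TestAlphaSelection:
    def test_singleton_grid_returned(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        assert select_alpha(X, y, grid=[0.3], n_groups=3, K=3, seed=0) == 0.3

    def test_noise_selection_is_total_and_deterministic(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        a1 = select_alpha(X, y, grid=[0.2, 0.8], n_groups=3, K=3, seed=5)
        a2 = select_alpha(X, y, grid=[0.2, 0.8], n_groups=3, K=3, seed=5)
        assert a1 == a2 and a1 in (0.2, 0.8)

    def test_too_many_groups_raises(self):
        with pytest.raises(ValidationError):
            select_alpha(np.ones((5, 2)), np.arange(5.0), n_groups=10)


class TestDerivation:
    def test_planted_pair_recovered_with_signs(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(500, 50)),
                         columns=[f"met_{j:03d}" for j in range(50)])
        y = X["met_000"].to_numpy() - X["met_001"].to_numpy()
        model = derive_signature(X, y, alpha=0.5, R=5, K=5, seed=0)
        counts = dict(zip(model.metabolites, model.selection_count))
        assert counts["met_000"] == 5 and counts["met_001"] == 5
        coef = dict(zip(model.metabolites, model.coef_avg))
        assert coef["met_000"] > 0 > coef["met_001"]
        # score on training data recovers the response almost perfectly
        pred = score_signature(model, X)
        assert np.corrcoef(pred, y)[0, 1] > 0.99

    def test_same_seed_reproduces_model(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(100, 10))
        y = X[:, 0] + rng.normal(size=100)
        m1 = derive_signature(X, y, alpha=0.5, R=3, K=4, seed=9)
        m2 = derive_signature(X, y, alpha=0.5, R=3, K=4, seed=9)
        np.testing.assert_array_equal(m1.coef_avg, m2.coef_avg)
        np.testing.assert_array_equal(m1.selection_count, m2.selection_count)
        assert m1.lambdas == m2.lambdas

    def test_zero_selection_count_implies_zero_average(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(120, 30))
        y = rng.normal(size=120)
        model = derive_signature(X, y, alpha=0.8, R=4, K=4, seed=2)
        zero_sel = model.selection_count == 0
        np.testing.assert_array_equal(model.coef_avg[zero_sel], 0.0)


class TestScoring:
    def test_all_zero_coefficients_give_constant(self):
        from hlmetsig.signature import SignatureModel

        model = SignatureModel(metabolites=["a", "b"], coef_avg=np.zeros(2),
                               intercept_avg=1.5, selection_count=np.zeros(2, int),
                               family="linear", alpha=0.5, R=3, K=3, seed=0)
        out = score_signature(model, np.random.default_rng(0).normal(size=(5, 2)))
        np.testing.assert_allclose(out, 1.5)

    def test_constant_shift_moves_scores_exactly(self):
        rng = np.random.default_rng(16)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + rng.normal(scale=0.1, size=50)
        model = derive_signature(X, y, alpha=0.5, R=2, K=3, seed=1)
        shift = score_signature(model, X + 2.0) - score_signature(model, X)
        np.testing.assert_allclose(shift, 2.0 * model.coef_avg.sum(), atol=1e-10)

    def test_misaligned_columns_name_the_mismatch(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        model = derive_signature(X, X["a"].to_numpy() + rng.normal(size=30),
                                 alpha=0.5, R=2, K=3, seed=0)
        with pytest.raises(DimensionError, match="'b'"):
            score_signature(model, X[["a", "c", "b"]])
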