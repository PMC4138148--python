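"""Solver correctness: objective, KKT certificates, oracle equivalence,
MLE limit, path structure."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import leadlasso as ll
from conftest import random_grouped_problem


def brute_force_solution(enc, lam, eps=1e-10):
    """Independent oracle: general-purpose convex minimizer of the penalized
    objective with an epsilon-smoothed group penalty."""
    y, X = enc.y, enc.X
    n = len(y)
    slices = enc.slices

    def objective(theta):
        b0, beta = theta[0], theta[1:]
        eta = b0 + X @ beta
        nll = np.mean(np.maximum(eta, 0) + np.log1p(np.exp(-np.abs(eta))) - y * eta)
        pen = sum(
            np.sqrt(int(enc.df[g])) * np.sqrt(beta[sl] @ beta[sl] + eps)
            for g, sl in enumerate(slices)
        )
        return nll + lam * pen

    best = None
    for x0 in (np.zeros(enc.p + 1), 0.1 * np.ones(enc.p + 1)):
        res = minimize(objective, x0, method="L-BFGS-B",
                       options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return best


class TestPredictProb:
    def test_null_model_half(self):
        fit = ll.solve_path(
            random_grouped_problem(np.random.default_rng(0), 50, [2]), lambdas=[10.0]
        ).fits[0]
        # force exact null for the check
        fit.coef = np.zeros_like(fit.coef)
        fit.intercept = 0.0
        assert ll.predict_prob(fit, [1.23, -4.5]) == 0.5

    def test_single_coefficient_hand_value(self):
        std = random_grouped_problem(np.random.default_rng(1), 50, [1])
        fit = ll.solve_path(std, lambdas=[0.01]).fits[0]
        fit.intercept, fit.coef = 0.0, np.array([np.log(2.28)])
        assert np.isclose(ll.predict_prob(fit, [1.0]), 0.695, atol=5e-4)

    def test_saturation_without_overflow(self):
        std = random_grouped_problem(np.random.default_rng(2), 30, [1])
        fit = ll.solve_path(std, lambdas=[0.01]).fits[0]
        fit.intercept, fit.coef = 0.0, np.array([1.0])
        assert ll.predict_prob(fit, [-800.0]) == 0.0
        assert ll.predict_prob(fit, [800.0]) == 1.0

    def test_dimension_mismatch(self):
        std = random_grouped_problem(np.random.default_rng(3), 30, [2])
        fit = ll.solve_path(std, lambdas=[0.01]).fits[0]
        with pytest.raises(ValueError):
            ll.predict_prob(fit, [1.0, 2.0, 3.0])


class TestPenalizedObjective:
    def test_null_objective_balanced(self):
        rng = np.random.default_rng(4)
        enc = random_grouped_problem(rng, 40, [2, 1])
        enc.y = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)]
        val = ll.penalized_objective(0.0, np.zeros(enc.p), enc, lam=0.3)
        assert np.isclose(val, np.log(2), atol=1e-12)

    def test_penalty_hand_value(self):
        rng = np.random.default_rng(5)
        enc = random_grouped_problem(rng, 40, [2, 3])
        beta = np.zeros(5)
        beta[:2] = [1.0, 0.0]       # ||g1|| = 1, df 2
        beta[2:] = [2.0, 0.0, 0.0]  # ||g2|| = 2, df 3
        with_pen = ll.penalized_objective(0.0, beta, enc, lam=0.1)
        without = ll.penalized_objective(0.0, beta, enc, lam=0.0)
        assert np.isclose(with_pen - without, 0.1 * (np.sqrt(2) + 2 * np.sqrt(3)),
                          atol=1e-12)

    def test_lambda_zero_is_plain_nll(self):
        rng = np.random.default_rng(6)
        enc = random_grouped_problem(rng, 40, [2, 2])
        beta = rng.normal(size=4)
        eta = 0.2 + enc.X @ beta
        nll = float(np.mean(np.log1p(np.exp(eta)) - enc.y * eta))
        assert np.isclose(ll.penalized_objective(0.2, beta, enc, 0.0), nll, atol=1e-10)


class TestLambdaMax:
    def test_constant_y_zero(self):
        rng = np.random.default_rng(7)
        enc = random_grouped_problem(rng, 40, [2, 2])
        enc.y = np.ones(40, dtype=int)
        assert ll.lambda_max(enc) == 0.0

    def test_fit_above_lambda_max_null(self, exposed_encoded):
        std = ll.standardize_groups(exposed_encoded)
        lmax = ll.lambda_max(std)
        fit = ll.fit_group_lasso(std, 1.01 * lmax)
        assert fit.active_groups == set()
        ybar = std.y.mean()
        assert np.isclose(fit.intercept_std, np.log(ybar / (1 - ybar)), atol=1e-5)
        # just below lambda_max something activates
        fit2 = ll.fit_group_lasso(std, 0.95 * lmax)
        assert len(fit2.active_groups) >= 1

    def test_singleton_reduces_to_classical_lasso_formula(self):
        rng = np.random.default_rng(8)
        enc = random_grouped_problem(rng, 60, [1])
        assert np.isclose(
            ll.lambda_max(enc),
            np.abs(enc.X[:, 0] @ (enc.y - enc.y.mean())) / enc.n,
            atol=1e-12,
        )


class TestFitGroupLasso:
    def test_monotone_descent_every_iteration(self):
        rng = np.random.default_rng(9)
        for sizes in ([2, 3], [1, 1, 4]):
            enc = random_grouped_problem(rng, 80, sizes, signal=rng.normal(size=sum(sizes)))
            fit = ll.fit_group_lasso(enc, 0.05, track_objective=True)
            path = np.asarray(fit.objective_path)
            assert np.all(np.diff(path) <= 1e-12)

    def test_kkt_certificate_random_problems(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            sizes = list(rng.integers(1, 4, size=rng.integers(2, 4)))
            enc = random_grouped_problem(
                rng, 60, sizes, signal=0.5 * rng.normal(size=sum(sizes))
            )
            lam = 0.3 * ll.lambda_max(enc) + 1e-4
            fit = ll.fit_group_lasso(enc, lam, tol=1e-10, max_iter=5000)
            assert ll.kkt_violation(fit, enc) < 1e-6

    def test_mle_limit_small_problem(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        enc = random_grouped_problem(rng, 200, [1] * 5, signal=0.5 * rng.normal(size=5))
        fit = ll.fit_group_lasso(enc, 1e-8, tol=1e-10, max_iter=20000)
        res = sm.Logit(enc.y, sm.add_constant(enc.X)).fit(disp=0)
        assert np.max(np.abs(fit.coef_std - res.params[1:])) < 1e-4
        assert abs(fit.intercept_std - res.params[0]) < 1e-4

    def test_oracle_equivalence_twenty_instances(self):
        rng = np.random.default_rng(12)
        worst = 0.0
        for i in range(20):
            sizes = list(rng.integers(1, 5, size=rng.integers(2, 4)))
            n = int(rng.integers(40, 101))
            enc = random_grouped_problem(
                rng, n, sizes, signal=rng.normal(size=sum(sizes))
            )
            lam = float(rng.uniform(0.05, 0.6)) * ll.lambda_max(enc)
            fit = ll.fit_group_lasso(enc, lam, tol=1e-10, max_iter=20000)
            oracle = brute_force_solution(enc, lam)
            mine = ll.penalized_objective(fit.intercept_std, fit.coef_std, enc, lam)
            gap = mine - oracle.fun
            worst = max(worst, gap)
            assert gap < 1e-5, f"instance {i}: objective gap {gap}"
        assert worst < 1e-5

    def test_group_permutation_invariance(self):
        rng = np.random.default_rng(13)
        enc = random_grouped_problem(rng, 80, [3, 2], signal=rng.normal(size=5))
        fit = ll.fit_group_lasso(enc, 0.03, tol=1e-10)
        # permute columns within group 0 and refit
        perm = np.array([2, 0, 1, 3, 4])
        enc2 = ll.EncodedDataset(
            y=enc.y, X=enc.X[:, perm],
            group_index=enc.group_index, group_names=enc.group_names,
            df=enc.df, column_names=[enc.column_names[j] for j in perm],
            row_ids=enc.row_ids,
        )
        enc2.standardization = enc.standardization
        fit2 = ll.fit_group_lasso(enc2, 0.03, tol=1e-10)
        n1, n2 = fit.group_norms, fit2.group_norms
        assert np.isclose(n1["g0"], n2["g0"], atol=1e-8)
        assert np.allclose(fit.coef_std[3:], fit2.coef_std[3:], atol=1e-8)
        assert np.allclose(fit.coef_std[perm[:3]], fit2.coef_std[:3], atol=1e-8)

    def test_nonconvergence_flagged(self):
        rng = np.random.default_rng(14)
        enc = random_grouped_problem(rng, 80, [2, 2], signal=rng.normal(size=4))
        fit = ll.fit_group_lasso(enc, 0.01, tol=1e-14, max_iter=3)
        assert not fit.converged and fit.n_iter == 3


class TestSolvePath:
    def test_first_entry_null(self, exposed_encoded):
        std = ll.standardize_groups(exposed_encoded)
        path = ll.solve_path(std, n_lambda=25, lambda_min_ratio=0.01)
        assert path.fits[0].active_groups == set()
        assert np.isclose(path.lambdas[0], path.lambda_max)
        assert np.all(np.diff(path.lambdas) < 0)

    def test_dominant_group_activates_first(self):
        rng = np.random.default_rng(15)
        signal = np.zeros(6)
        signal[2:4] = [2.0, -2.0]  # group 1 carries all the signal
        enc = random_grouped_problem(rng, 400, [2, 2, 2], signal=signal)
        path = ll.solve_path(enc, n_lambda=60, lambda_min_ratio=0.01)
        first_active = next(f for f in path.fits if f.active_groups)
        assert first_active.active_groups == {"g1"}

    def test_deterministic(self, exposed_encoded):
        std = ll.standardize_groups(exposed_encoded)
        a = ll.solve_path(std, n_lambda=15, lambda_min_ratio=0.05)
        b = ll.solve_path(std, n_lambda=15, lambda_min_ratio=0.05)
        for fa, fb in zip(a.fits, b.fits):
            assert np.array_equal(fa.coef_std, fb.coef_std)

    def test_penalty_norm_monotone_in_lambda(self, exposed_encoded):
        std = ll.standardize_groups(exposed_encoded)
        path = ll.solve_path(std, n_lambda=30, lambda_min_ratio=0.01)
        pens = [
            sum(np.sqrt(int(f.df[g])) * np.linalg.norm(f.coef_std[sl])
                for g, sl in enumerate(f.slices))
            for f in path.fits
        ]
        assert np.all(np.diff(pens) >= -1e-8)  # decreasing lambda grows the fit

    def test_engines_agree(self, exposed_encoded):
        std = ll.standardize_groups(exposed_encoded)
        kern = ll.solve_path(std, n_lambda=12, lambda_min_ratio=0.05)
        py = ll.solve_path(std, n_lambda=12, lambda_min_ratio=0.05, engine="python")
        for fk, fp in zip(kern.fits, py.fits):
            assert abs(fk.objective - fp.objective) < 1e-9
            assert np.max(np.abs(fk.coef_std - fp.coef_std)) < 1e-6


class TestLogisticMLE:
    def test_cross_product_odds_ratio_from_counts(self):
        # 2x2 exposure table expanded to records: slope = log cross-product ratio
        y = np.r_[np.zeros(409), np.ones(70), np.zeros(221), np.ones(92)].astype(int)
        x = np.r_[np.zeros(479), np.ones(313)]
        enc = ll.EncodedDataset(
            y=y, X=x[:, None], group_index=np.zeros(1, dtype=int),
            group_names=["exposure"], df=np.array([1]), column_names=["exposure[yes]"],
            row_ids=np.arange(len(y)),
        )
        fit = ll.fit_logistic_mle(enc)
        assert np.isclose(fit.coef[0], np.log((92 * 409) / (70 * 221)), atol=1e-6)
        assert np.isclose(fit.odds_ratios[0], 2.432, atol=1e-3)

    def test_null_wald_p_uniform(self):
        rng = np.random.default_rng(16)
        n, p = 10_000, 4
        X = rng.normal(size=(n, p))
        y = rng.integers(0, 2, size=n)
        enc = ll.EncodedDataset(
            y=y, X=X, group_index=np.arange(p), group_names=[f"g{i}" for i in range(p)],
            df=np.ones(p, dtype=int), column_names=[f"c{i}" for i in range(p)],
            row_ids=np.arange(n),
        )
        fit = ll.fit_logistic_mle(enc)
        assert (fit.p_values > 0.001).all()  # no spurious strong signal

    def test_intercept_only(self):
        rng = np.random.default_rng(17)
        n = 500
        y = (rng.random(n) < 0.3).astype(int)
        x = rng.normal(size=(n, 1))  # noise column with no effect
        enc = ll.EncodedDataset(
            y=y, X=x, group_index=np.zeros(1, dtype=int), group_names=["g"],
            df=np.array([1]), column_names=["c"], row_ids=np.arange(n),
        )
        fit = ll.fit_logistic_mle(enc)
        ybar = y.mean()
        assert abs(fit.intercept - np.log(ybar / (1 - ybar))) < 0.1

    def test_separation_raises(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        enc = ll.EncodedDataset(
            y=y, X=x[:, None], group_index=np.zeros(1, dtype=int), group_names=["g"],
            df=np.array([1]), column_names=["c"], row_ids=np.arange(40),
        )
        with pytest.raises(ll.SeparationError):
            ll.fit_logistic_mle(enc)

    def test_or_equals_exp_coef(self, exposed_encoded):
        red, _ = ll.encode.reduce_collinear(exposed_encoded)
        fit = ll.fit_logistic_mle(red)
        assert np.allclose(fit.odds_ratios, np.exp(fit.coef), rtol=1e-12)
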