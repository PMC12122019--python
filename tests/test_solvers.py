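import numpy as np
import pytest
from scipy.optimize import minimize

from sparsevda.objective import (epsilon_risk, penalized_objective,
                                 surrogate_responses, surrogate_value)
from sparsevda.projections import Constraint
from sparsevda.solvers import (AnnealingSchedule, SolverControls,
                               build_svd_cache, continuation_ladder,
                               fit_unconstrained, inner_solve,
                               mm_direct_update, proximal_distance_fit,
                               proximal_distance_path,
                               steepest_descent_update)
from tests.conftest import random_design


def _state(B, X, Y, eps, cons):
    state = surrogate_responses(B, X, Y, eps)
    state.P = cons.project(B) if cons is not None else None
    return state


class TestSVDCache:
    def test_identity_design(self):
        cache = build_svd_cache(np.eye(4))
        assert np.allclose(cache.singular_values, 1.0)
        assert cache.r == 4

    def test_reconstruction(self, rng):
        X = rng.standard_normal((20, 5))
        cache = build_svd_cache(X)
        recon = cache.U @ np.diag(cache.singular_values) @ cache.V.T
        assert np.linalg.norm(recon - X) < 1e-10
        assert np.allclose(cache.U.T @ cache.U, np.eye(cache.r), atol=1e-10)
        assert np.allclose(cache.V.T @ cache.V, np.eye(cache.r), atol=1e-10)

    def test_rank_one_design(self, rng):
        u = rng.standard_normal(10)
        v = rng.standard_normal(4)
        assert build_svd_cache(np.outer(u, v)).r == 1

    def test_non_finite_rejected(self):
        X = np.ones((3, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            build_svd_cache(X)


class TestDirectUpdate:
    def test_identity_design_scalar_formula(self, rng):
        n = 4
        X = np.eye(n)
        Y = rng.standard_normal((n, 2))
        B = rng.standard_normal((n, 2))
        cons = Constraint(variant="row_sparse", k=2)
        state = _state(B, X, Y, 0.3, cons)
        rho = 1.7
        got = mm_direct_update(state, X, rho)
        expected = (state.Z / n + rho * state.P) / (1 / n + rho)
        assert np.allclose(got, expected, atol=1e-10)

    def test_huge_rho_returns_projection(self, rng):
        X, Y = random_design(rng, 10, 4, 2)
        B = rng.standard_normal((4, 2))
        cons = Constraint(variant="row_sparse", k=2)
        state = _state(B, X, Y, 0.3, cons)
        got = mm_direct_update(state, X, 1e8, cache=build_svd_cache(X))
        assert np.allclose(got, state.P, atol=1e-6)

    @pytest.mark.parametrize("shape", [(30, 8), (8, 30), (20, 20)])
    def test_woodbury_path_matches_dense_solve(self, rng, shape):
        n, p = shape
        X, Y = random_design(rng, n, p, 3)
        B = rng.standard_normal((p, 3))
        cons = Constraint(variant="row_sparse", k=3)
        state = _state(B, X, Y, 0.3, cons)
        for rho in (1e-3, 1.0, 50.0):
            dense = mm_direct_update(state, X, rho, cache=None)
            fast = mm_direct_update(state, X, rho, cache=build_svd_cache(X))
            assert np.linalg.norm(dense - fast) <= \
                1e-8 * max(1.0, np.linalg.norm(dense))

    def test_result_is_surrogate_stationary(self, rng):
        X, Y = random_design(rng, 15, 5, 2)
        B = rng.standard_normal((5, 2))
        cons = Constraint(variant="row_sparse", k=2)
        state = _state(B, X, Y, 0.3, cons)
        rho = 2.0
        B_new = mm_direct_update(state, X, rho, cache=build_svd_cache(X))
        grad = -X.T @ (state.Z - X @ B_new) / 15 + rho * (B_new - state.P)
        assert np.linalg.norm(grad) < 1e-8

    def test_nonpositive_rho_rejected(self, rng):
        X, Y = random_design(rng, 6, 3, 2)
        cons = Constraint(variant="row_sparse", k=1)
        state = _state(np.zeros((3, 2)), X, Y, 0.3, cons)
        with pytest.raises(ValueError):
            mm_direct_update(state, X, 0.0)


class TestSteepestDescent:
    def test_zero_gradient_no_move(self, rng):
        X = np.zeros((4, 3))
        Y = np.zeros((4, 2))
        B = np.zeros((3, 2))
        cons = Constraint(variant="row_sparse", k=3)
        state = _state(B, X, Y, 0.3, cons)
        B_new, step = steepest_descent_update(state, X, 1.0,
                                              G=np.zeros((3, 2)))
        assert step == 0.0
        assert np.array_equal(B_new, B)

    def test_degenerate_design_step_is_inverse_rho(self, rng):
        X = np.zeros((4, 3))
        Y = np.ones((4, 2))
        B = rng.standard_normal((3, 2))
        cons = Constraint(variant="row_sparse", k=1)
        state = _state(B, X, Y, 0.0, cons)
        rho = 2.5
        G = rho * (B - state.P)
        _, step = steepest_descent_update(state, X, rho, G=G)
        assert step == pytest.approx(1 / rho)

    def test_step_is_exact_line_minimizer(self, rng):
        X, Y = random_design(rng, 12, 5, 3)
        B = rng.standard_normal((5, 3))
        cons = Constraint(variant="row_sparse", k=2)
        state = _state(B, X, Y, 0.3, cons)
        rho = 1.3
        from sparsevda.objective import surrogate_gradient
        G = surrogate_gradient(B, state, X, rho)
        B_star, gamma = steepest_descent_update(state, X, rho, G=G)
        val_star = surrogate_value(B_star, state, X, rho)
        for gprime in np.linspace(0, 2 * gamma, 50):
            val = surrogate_value(B - gprime * G, state, X, rho)
            assert val_star <= val + 1e-12


class TestInnerSolve:
    def test_stationary_start_returns_immediately(self, rng):
        X, Y = random_design(rng, 20, 4, 2)
        cons = Constraint(variant="row_sparse", k=2)
        controls = SolverControls(grad_tol=1e-8, max_inner=500)
        B, info = inner_solve(np.zeros((4, 2)), X, Y, 0.3, cons, 1.0,
                              controls)
        assert info["grad_ok"]
        B2, info2 = inner_solve(B, X, Y, 0.3, cons, 1.0, controls)
        assert info2["n_iter"] == 0
        assert np.array_equal(B2, B)

    @pytest.mark.parametrize("method", ["direct", "steepest"])
    def test_objective_descends_without_acceleration(self, rng, method):
        cons = Constraint(variant="row_sparse", k=2)
        controls = SolverControls(grad_tol=1e-9, max_inner=300, accel=False)
        for _ in range(10):
            X, Y = random_design(rng, 15, 5, 3)
            B0 = rng.standard_normal((5, 3))
            _, info = inner_solve(B0, X, Y, 0.3, cons, 0.7, controls,
                                  method=method)
            trace = np.array(info["trace"])
            assert np.all(np.diff(trace) <= 1e-10)

    def test_accelerated_trace_descends_after_restarts(self, rng):
        cons = Constraint(variant="row_sparse", k=2)
        controls = SolverControls(grad_tol=1e-9, max_inner=300, accel=True)
        for _ in range(10):
            X, Y = random_design(rng, 15, 5, 3)
            B0 = rng.standard_normal((5, 3))
            _, info = inner_solve(B0, X, Y, 0.3, cons, 0.7, controls)
            trace = np.array(info["trace"])
            assert np.all(np.diff(trace) <= 1e-10)

    def test_both_update_rules_reach_same_stationary_point(self, rng):
        X, Y = random_design(rng, 40, 5, 2)
        cons = Constraint(variant="row_sparse", k=3)
        controls = SolverControls(grad_tol=1e-9, max_inner=5000)
        B_direct, _ = inner_solve(np.zeros((5, 2)), X, Y, 0.3, cons, 2.0,
                                  controls, method="direct")
        B_steep, _ = inner_solve(np.zeros((5, 2)), X, Y, 0.3, cons, 2.0,
                                 controls, method="steepest")
        assert np.linalg.norm(B_direct - B_steep) < 1e-5

    def test_unconstrained_matches_generic_optimizer(self, rng):
        # overdetermined: the minimizer of the plain risk is well defined
        X, Y = random_design(rng, 30, 4, 3)
        eps = 0.3
        B = fit_unconstrained(X, Y, eps, grad_tol=1e-10, max_iter=2000)
        res = minimize(
            lambda b: epsilon_risk(b.reshape(4, 3), X, Y, eps),
            np.zeros(12), method="L-BFGS-B",
            options={"ftol": 1e-14, "gtol": 1e-10})
        assert epsilon_risk(B, X, Y, eps) == pytest.approx(res.fun, abs=1e-4)


class TestProximalDistanceFit:
    def test_vacuous_constraint_exits_immediately(self, rng):
        X, Y = random_design(rng, 20, 4, 2)
        cons = Constraint(variant="row_sparse", k=4)
        result = proximal_distance_fit(X, Y, 0.3, cons)
        assert result.converged
        assert result.n_outer == 1
        assert result.dist_trace[0] == 0.0

    def test_separable_toy_recovers_informative_features(self, rng):
        # 2 informative of 10 features, two widely separated blobs
        n = 60
        X = rng.standard_normal((n, 10))
        y = np.repeat([0, 1], n // 2)
        X[:, 3] += np.where(y == 0, 4.0, -4.0)
        X[:, 7] += np.where(y == 0, -4.0, 4.0)
        Y = np.zeros((n, 2))
        Y[np.arange(n), y] = 1.0
        design = np.column_stack([np.ones(n), X])
        cons = Constraint(variant="row_sparse", k=2, exclude_intercept=True)
        result = proximal_distance_fit(design, Y, 0.3, cons)
        assert set(result.support) == {3, 7}
        pred = np.argmax(design @ result.B, axis=1)
        assert np.mean(pred != y) == 0.0

    def test_final_iterate_is_exactly_feasible(self, rng):
        cons = Constraint(variant="row_sparse", k=2)
        for _ in range(20):
            X, Y = random_design(rng, 25, 6, 3)
            result = proximal_distance_fit(X, Y, 0.3, cons)
            assert cons.distance(result.B) == 0.0
            assert np.all(np.isfinite(result.dist_trace))

    def test_polish_keeps_support_and_does_not_hurt_risk(self, rng):
        X, Y = random_design(rng, 40, 8, 2)
        cons = Constraint(variant="row_sparse", k=3)
        plain = proximal_distance_fit(X, Y, 0.3, cons, polish=False)
        polished = proximal_distance_fit(X, Y, 0.3, cons, polish=True)
        assert set(polished.support) == set(plain.support)
        assert epsilon_risk(polished.B, X, Y, 0.3) <= \
            epsilon_risk(plain.B, X, Y, 0.3) + 1e-12


class TestContinuation:
    def test_ladder_is_decreasing_and_ends_at_target(self):
        ladder = continuation_ladder(1000, 30)
        assert ladder[-1] == 30
        assert all(a > b for a, b in zip(ladder, ladder[1:]))
        assert all(30 < v < 1000 for v in ladder[:-1])

    def test_path_results_are_feasible_at_each_size(self, rng):
        X, Y = random_design(rng, 30, 8, 2)
        results = proximal_distance_path(X, Y, 0.3, [6, 4, 2],
                                         variant="row_sparse",
                                         exclude_intercept=False)
        for k, res in results.items():
            cons = Constraint(variant="row_sparse", k=k)
            assert cons.distance(res.B) == 0.0
            assert len(res.support) <= k
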