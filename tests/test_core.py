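"""Unit tests for the composite objective, its pieces, and the solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from exprmtl import core
from exprmtl.core import (
    FitOptions,
    fit_fista,
    l21_norm,
    logistic_loss,
    loss_gradient,
    objective_value,
    predict_labels,
    predict_proba,
    prox_l21,
)
from exprmtl.data import build_tasks


def brute_force_loss(X, y, w, c):
    """Independent term-by-term evaluation of the mean logistic loss."""
    total = 0.0
    for k in range(len(y)):
        margin = y[k] * (float(np.dot(X[k], w)) + c)
        total += math.log(1.0 + math.exp(-margin))
    return total / len(y)


class TestLogisticLoss:
    def test_zero_parameters_give_ln2(self, rng):
        X = rng.normal(size=(7, 3))
        y = np.array([1, -1, 1, 1, -1, -1, 1.0])
        assert logistic_loss(X, y, np.zeros(3), 0.0) == pytest.approx(math.log(2), abs=1e-12)

    def test_single_forced_term(self):
        # margin 10 -> log(1 + e^{-10})
        val = logistic_loss([[1.0]], [1.0], [10.0], 0.0)
        assert val == pytest.approx(math.log(1 + math.exp(-10)), rel=1e-12)
        assert val == pytest.approx(4.5398e-5, rel=1e-4)

    def test_matches_elementwise_oracle(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.choice([-1.0, 1.0], size=5)
        w = rng.normal(size=3)
        c = float(rng.normal())
        assert logistic_loss(X, y, w, c) == pytest.approx(
            brute_force_loss(X, y, w, c), abs=1e-12
        )

    def test_stable_for_huge_margins(self):
        # a naive exp() would overflow at margin -1000
        val = logistic_loss([[1.0]], [-1.0], [1000.0], 0.0)
        assert val == pytest.approx(1000.0, rel=1e-12)
        assert logistic_loss([[1.0]], [1.0], [1000.0], 0.0) == 0.0

    def test_rejects_bad_labels_and_shapes(self):
        with pytest.raises(ValueError, match=r"\+1/-1"):
            logistic_loss([[1.0]], [0.5], [1.0], 0.0)
        with pytest.raises(ValueError, match="length 2"):
            logistic_loss([[1.0]], [1.0, -1.0], [1.0], 0.0)
        with pytest.raises(ValueError, match="expected p=1"):
            logistic_loss([[1.0]], [1.0], [1.0, 2.0], 0.0)


class TestL21Norm:
    def test_zero_matrix(self):
        assert l21_norm(np.zeros((4, 3))) == 0.0

    def test_pythagorean_row(self):
        assert l21_norm(np.array([[3.0, 4.0]])) == pytest.approx(5.0, abs=1e-15)

    def test_matches_row_by_row_oracle(self, rng):
        W = rng.normal(size=(6, 4))
        oracle = sum(math.sqrt(sum(x * x for x in row)) for row in W)
        assert l21_norm(W) == pytest.approx(oracle, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            l21_norm(np.empty((0, 0)))


class TestObjective:
    def test_zero_model_gives_t_ln2(self, rng):
        X = rng.normal(size=(8, 4))
        Y = np.where(rng.random((8, 3)) > 0.5, 1.0, -1.0)
        val = objective_value(X, Y, np.zeros((4, 3)), np.zeros(3), 0.0, 0.0)
        assert val == pytest.approx(3 * math.log(2), abs=1e-12)

    def test_no_penalty_equals_sum_of_losses(self, rng):
        X = rng.normal(size=(8, 4))
        Y = np.where(rng.random((8, 3)) > 0.5, 1.0, -1.0)
        W = rng.normal(size=(4, 3))
        C = rng.normal(size=3)
        loss_sum = sum(logistic_loss(X, Y[:, i], W[:, i], C[i]) for i in range(3))
        assert objective_value(X, Y, W, C, 0.0, 0.0) == pytest.approx(loss_sum, abs=1e-12)

    def test_matches_term_by_term_assembly(self, rng):
        X = rng.normal(size=(8, 4))
        Y = np.where(rng.random((8, 3)) > 0.5, 1.0, -1.0)
        W = rng.normal(size=(4, 3))
        C = rng.normal(size=3)
        lam1, lam2 = 0.3, 0.07
        oracle = (
            sum(brute_force_loss(X, Y[:, i], W[:, i], C[i]) for i in range(3))
            + lam1 * sum(math.sqrt(sum(x * x for x in row)) for row in W)
            + lam2 * float((W * W).sum())
        )
        assert objective_value(X, Y, W, C, lam1, lam2) == pytest.approx(oracle, abs=1e-10)

    def test_shape_disagreement_rejected(self, rng):
        X = rng.normal(size=(8, 4))
        Y = np.where(rng.random((8, 3)) > 0.5, 1.0, -1.0)
        with pytest.raises(ValueError, match="W has shape"):
            objective_value(X, Y, np.zeros((5, 3)), np.zeros(3), 0.0, 0.0)


def finite_difference_gradient(X, Y, W, C, h=1e-6):
    """Central finite differences of the summed per-task mean losses."""

    def value(Wv, Cv):
        return sum(
            logistic_loss(X, Y[:, i], Wv[:, i], Cv[i]) for i in range(Y.shape[1])
        )

    gW = np.zeros_like(W)
    for j in range(W.shape[0]):
        for i in range(W.shape[1]):
            up, dn = W.copy(), W.copy()
            up[j, i] += h
            dn[j, i] -= h
            gW[j, i] = (value(up, C) - value(dn, C)) / (2 * h)
    gC = np.zeros_like(C)
    for i in range(C.shape[0]):
        up, dn = C.copy(), C.copy()
        up[i] += h
        dn[i] -= h
        gC[i] = (value(W, up) - value(W, dn)) / (2 * h)
    return gW, gC


class TestLossGradient:
    def test_two_point_symmetric_case(self):
        # sigma(0) = 1/2 at W=0: dL/dW = -(1/2)(1/2)(1*1 + (-1)(-1)) = -1/2
        gW, gC = loss_gradient(
            np.array([[1.0], [-1.0]]), np.array([[1.0], [-1.0]]), np.zeros((1, 1)), np.zeros(1)
        )
        assert gW[0, 0] == pytest.approx(-0.5, abs=1e-15)
        assert gC[0] == pytest.approx(0.0, abs=1e-15)

    def test_gradient_vanishes_when_separable_and_scaled_up(self, rng):
        X = rng.normal(size=(6, 2))
        w = rng.normal(size=2)
        y = np.sign(X @ w + 0.1)[:, None]
        W = 1e4 * w[:, None]  # all margins -> +inf
        gW, gC = loss_gradient(X, y, W, np.zeros(1))
        assert np.linalg.norm(gW) < 1e-10
        assert np.linalg.norm(gC) < 1e-10

    def test_matches_central_finite_differences(self, rng):
        X = rng.normal(size=(10, 5))
        Y = np.where(rng.random((10, 3)) > 0.5, 1.0, -1.0)
        W = rng.normal(size=(5, 3))
        C = rng.normal(size=3)
        gW, gC = loss_gradient(X, Y, W, C)
        fW, fC = finite_difference_gradient(X, Y, W, C)
        assert np.allclose(gW, fW, rtol=1e-5, atol=1e-8)
        assert np.allclose(gC, fC, rtol=1e-5, atol=1e-8)


class TestProxL21:
    def test_tau_zero_is_identity(self, rng):
        W = rng.normal(size=(5, 3))
        assert np.array_equal(prox_l21(W, 0.0), W)

    def test_row_at_threshold_is_zeroed(self):
        out = prox_l21(np.array([[0.3, 0.4]]), 0.5)
        assert np.array_equal(out, np.zeros((1, 2)))

    def test_345_row_shrinks_to_closed_form(self):
        out = prox_l21(np.array([[3.0, 4.0]]), 1.0)
        assert np.allclose(out, [[2.4, 3.2]], atol=1e-12)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            prox_l21(np.zeros((1, 1)), -0.1)

    @pytest.mark.parametrize("dim", [1, 2, 4])
    def test_beats_generic_minimizer_and_random_candidates(self, dim, rng):
        for _ in range(5):
            w = rng.normal(size=dim)
            tau = float(rng.uniform(0, 2))
            u_star = prox_l21(w[None, :], tau)[0]

            def prox_objective(u):
                return 0.5 * float(((u - w) ** 2).sum()) + tau * float(
                    np.linalg.norm(u)
                )

            ours = prox_objective(u_star)
            res = minimize(prox_objective, w, method="Nelder-Mead", options={"fatol": 1e-12, "xatol": 1e-12})
            assert ours <= res.fun + 1e-8
            cands = w + rng.normal(scale=0.5, size=(100_000, dim))
            cand_obj = 0.5 * ((cands - w) ** 2).sum(axis=1) + tau * np.linalg.norm(cands, axis=1)
            assert ours <= cand_obj.min() + 1e-12

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=4), st.floats(0, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_row_norm_shrinks_by_exactly_tau(self, row, tau):
        w = np.array([row])
        out = prox_l21(w, tau)
        expected = max(0.0, np.linalg.norm(w) - tau)
        assert np.linalg.norm(out) == pytest.approx(expected, abs=1e-9)


class TestFit:
    def test_intercept_only_limit_at_large_lambda1(self, rng):
        X = rng.normal(size=(40, 6))
        labels = ["A"] * 20 + ["B"] * 12 + ["C"] * 8
        from exprmtl.data import ExpressionDataset

        data = ExpressionDataset(
            X=X,
            sample_ids=[f"s{i}" for i in range(40)],
            gene_ids=[f"g{j}" for j in range(6)],
            labels=labels,
        )
        ts = build_tasks(data)
        gW, _ = loss_gradient(ts.X, ts.Y, np.zeros((6, 3)), np.zeros(3))
        lam1 = 10.0 * float(np.linalg.norm(gW, axis=1).max())
        W, C, trace = fit_fista(
            ts.X, ts.Y, lam1, 0.0, FitOptions(tolerance=1e-12, max_iterations=20000)
        )
        assert np.array_equal(W, np.zeros((6, 3)))
        n_pos = np.array([20, 12, 8])
        expected = np.log(n_pos / (40 - n_pos))
        assert np.allclose(C, expected, atol=1e-4)

    def test_single_task_matches_generic_optimizer_smooth(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.sign(X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(scale=0.5, size=30))
        Y = y[:, None]
        lam2 = 1e-3
        W, C, trace = fit_fista(X, Y, 0.0, lam2, FitOptions(tolerance=1e-14, max_iterations=20000))
        ours = objective_value(X, Y, W, C, 0.0, lam2)

        def scalar_objective(theta):
            return objective_value(X, Y, theta[:4][:, None], theta[4:], 0.0, lam2)

        res = minimize(scalar_objective, np.zeros(5), method="L-BFGS-B",
                       options={"ftol": 1e-15, "gtol": 1e-12})
        assert abs(ours - res.fun) < 1e-6

    def test_trace_is_monotone_and_converges(self, fitted_results):
        obj = np.asarray(fitted_results.trace.objective_values)
        assert np.all(np.diff(obj) <= 0)
        assert fitted_results.trace.converged
        assert fitted_results.trace.n_iterations <= 5000
        # starts from the analytic zero-initialization value: t * ln 2 + 0
        assert obj[0] == pytest.approx(6 * math.log(2), abs=1e-12)

    def test_nonfinite_predictors_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        Y = np.array([[1.0], [-1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            fit_fista(X, Y, 0.0, 0.0, FitOptions())

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(40, 12))
        Y = np.where(rng.random((40, 3)) > 0.6, 1.0, -1.0)
        opts = FitOptions(tolerance=1e-10, max_iterations=10000)
        W1, C1, _ = fit_fista(X, Y, 0.05, 1e-4, opts)
        perm = rng.permutation(12)
        W2, C2, _ = fit_fista(X[:, perm], Y, 0.05, 1e-4, opts)
        assert np.allclose(W2, W1[perm], atol=1e-6)
        obj1 = objective_value(X, Y, W1, C1, 0.05, 1e-4)
        obj2 = objective_value(X[:, perm], Y, W2, C2, 0.05, 1e-4)
        assert abs(obj1 - obj2) < 1e-8


class TestPredict:
    def test_zero_model_gives_half_everywhere(self, rng):
        proba = predict_proba(np.zeros((4, 3)), np.zeros(3), rng.normal(size=(6, 4)))
        assert np.allclose(proba, 0.5)

    def test_large_intercept_saturates(self, rng):
        proba = predict_proba(np.zeros((4, 2)), np.array([50.0, 0.0]), rng.normal(size=(5, 4)))
        assert np.allclose(proba[:, 0], 1.0)

    def test_matches_sigmoid_oracle(self, rng):
        W = rng.normal(size=(4, 3))
        C = rng.normal(size=3)
        X = rng.normal(size=(6, 4))
        oracle = 1.0 / (1.0 + np.exp(-(X @ W + C)))
        assert np.allclose(predict_proba(W, C, X), oracle, atol=1e-12)

    def test_gene_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="genes"):
            predict_proba(np.zeros((4, 2)), np.zeros(2), rng.normal(size=(3, 5)))

    def test_argmax_labels_and_flags(self):
        labels, flags = predict_labels(
            np.array([[0.9, 0.2, 0.1], [0.4, 0.4, 0.4]]), ["A", "B", "C"]
        )
        assert labels == ["A", "A"]  # tie in row 2 breaks to lowest index
        assert flags.tolist() == [False, True]

    def test_empty_proba_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            predict_labels(np.empty((0, 3)), ["A", "B", "C"])

    def test_recovers_truth_on_separated_synthetic_data(self, fitted_results, standard_split):
        test = standard_split.test
        labels = fitted_results.predict(test.X)
        agree = np.mean([a == b for a, b in zip(labels, test.labels)])
        assert agree >= 0.95
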