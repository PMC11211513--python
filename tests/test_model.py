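import numpy as np
import pytest
from scipy.optimize import minimize

from twingp import (ILSTSVR, LSTSVR, ILSTSVRHyperparams, fit_ilstsvr,
                    fit_lstsvr, solve_twin_side, twin_objective, update_alpha)
from twingp.model import assemble_twin_system


def _oracle_minimum(H, Y, C, C_reg, eps, alpha, side):
    p = np.asarray(H).shape[1]
    f = lambda z: twin_objective(H, Y, C, C_reg, eps, alpha, side,
                                 z[:-1], z[-1])
    res = minimize(f, np.zeros(p + 1), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 5000})
    return res.fun


class TestSolveTwinSide:
    def test_exact_fit_minimizer(self):
        # y = 2x fits both quadratic terms exactly at (w, b) = (2, 0)
        w, b = solve_twin_side([[1], [2], [3]], [2, 4, 6], C=1.0, C_reg=0.0,
                               eps=0.0, alpha=[1.0], side="down")
        assert w[0] == pytest.approx(2.0)
        assert b == pytest.approx(0.0, abs=1e-10)

    def test_zero_target_shrinks_to_origin(self, rng):
        H = rng.normal(size=(6, 3))
        w, b = solve_twin_side(H, np.zeros(6), C=1.0, C_reg=1.0, eps=0.0,
                               alpha=np.ones(3), side="up")
        np.testing.assert_allclose(w, 0.0, atol=1e-12)
        assert b == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("side", ["down", "up"])
    def test_matches_numerical_minimizer(self, rng, side):
        H = rng.normal(size=(6, 3))
        Y = rng.normal(size=6)
        alpha = rng.uniform(0.5, 2.0, size=3)
        w, b = solve_twin_side(H, Y, C=2.0, C_reg=0.5, eps=0.1,
                               alpha=alpha, side=side)
        mine = twin_objective(H, Y, 2.0, 0.5, 0.1, alpha, side, w, b)
        ref = _oracle_minimum(H, Y, 2.0, 0.5, 0.1, alpha, side)
        assert mine <= ref * (1 + 1e-6) + 1e-12

    def test_gradient_vanishes_at_solution(self, rng):
        H = rng.normal(size=(8, 4))
        Y = rng.normal(size=8)
        alpha = rng.uniform(0.5, 2.0, size=4)
        sys = assemble_twin_system(H, Y, 3.0, 0.7, 0.05, alpha, "down")
        w, b = solve_twin_side(H, Y, 3.0, 0.7, 0.05, alpha, "down")
        grad = sys.lhs @ np.concatenate([w, [b]]) - sys.rhs
        assert np.linalg.norm(grad) <= 1e-6 * (1 + np.linalg.norm(sys.rhs))

    def test_system_is_symmetric(self, rng):
        H = rng.normal(size=(5, 3))
        sys = assemble_twin_system(H, rng.normal(size=5), 1.5, 0.2, 0.1,
                                   np.ones(3), "up")
        np.testing.assert_allclose(sys.lhs, sys.lhs.T, rtol=1e-12)

    def test_invalid_inputs(self, rng):
        H = rng.normal(size=(4, 2))
        with pytest.raises(ValueError):
            solve_twin_side(H, np.zeros(4), 1.0, 0.0, 0.0, [1.0, -1.0], "down")
        with pytest.raises(ValueError, match="non-finite"):
            solve_twin_side(H, [np.nan, 0, 0, 0], 1.0, 0.0, 0.0,
                            [1.0, 1.0], "down")
        with pytest.raises(ValueError, match="side"):
            solve_twin_side(H, np.zeros(4), 1.0, 0.0, 0.0, [1, 1], "middle")


class TestUpdateAlpha:
    def test_reciprocal_of_magnitude(self):
        np.testing.assert_allclose(update_alpha([2.0]), [0.5])
        np.testing.assert_allclose(update_alpha([-0.5]), [2.0])

    def test_floor_guards_zero_weights(self):
        np.testing.assert_allclose(update_alpha([0.0], floor=1e-8), [1e8])

    def test_entries_positive_and_bounded(self, rng):
        a = update_alpha(rng.normal(size=50), floor=1e-8)
        assert (a > 0).all() and (a <= 1e8).all()


class TestHyperparams:
    @pytest.mark.parametrize("kwargs", [
        {"C1": 0.0}, {"C1": -1.0}, {"C3": -0.1}, {"eps1": -0.01},
        {"kernel": "poly"}, {"kernel": "rbf"}, {"kernel": "rbf", "sigma": -1},
    ])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ILSTSVRHyperparams(**kwargs)

    def test_penalties_are_tied(self):
        hp = ILSTSVRHyperparams(C1=3.0, C3=0.7)
        assert hp.C2 == hp.C1 and hp.C4 == hp.C3


class TestFitting:
    def test_lstsvr_reduction_any_alpha_init(self, small_xy):
        X, y = small_xy
        hp = ILSTSVRHyperparams(C1=2.0, C3=0.0, eps1=0.1, eps2=0.2)
        ref = fit_lstsvr(X, y, hp)
        for init, seed in [("ones", None), ("random", 3), ("random", 99)]:
            res = ILSTSVR(y, X, hp).fit(alpha_init=init, seed=seed)
            np.testing.assert_allclose(res.w1, ref.w1, rtol=1e-8)
            np.testing.assert_allclose(res.w2, ref.w2, rtol=1e-8)
            assert res.b1 == pytest.approx(ref.b1, rel=1e-8)
            assert res.b2 == pytest.approx(ref.b2, rel=1e-8)

    def test_lstsvr_matches_oracle_objective(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        hp = ILSTSVRHyperparams(C1=1.5, C3=0.0, eps1=0.05, eps2=0.05)
        res = fit_lstsvr(X, y, hp)
        mine = twin_objective(X, y, 1.5, 0.0, 0.05, np.ones(4), "down",
                              res.w1, res.b1)
        ref = _oracle_minimum(X, y, 1.5, 0.0, 0.05, np.ones(4), "down")
        assert mine <= ref * (1 + 1e-6) + 1e-12

    def test_symmetric_bounds_coincide_at_zero_eps(self, small_xy):
        X, y = small_xy
        res = fit_ilstsvr(X, y, ILSTSVRHyperparams(C1=3.0, C3=0.8,
                                                   eps1=0.0, eps2=0.0))
        np.testing.assert_allclose(res.w1, res.w2, atol=1e-8)
        assert res.b1 == pytest.approx(res.b2, abs=1e-8)

    def test_surrogate_objective_decreases_across_iterations(self, small_xy):
        # each alternating solve is an exact minimization at the current
        # alpha, so re-solving can only lower that side's surrogate objective
        X, y = small_xy
        hp = ILSTSVRHyperparams(C1=2.0, C3=1.0, eps1=0.05, eps2=0.05)
        alpha = np.ones(X.shape[1])
        w, b = np.zeros(X.shape[1]), 0.0
        for _ in range(5):
            before = twin_objective(X, y, hp.C1, hp.C3, hp.eps1, alpha,
                                    "down", w, b)
            w, b = solve_twin_side(X, y, hp.C1, hp.C3, hp.eps1, alpha, "down")
            after = twin_objective(X, y, hp.C1, hp.C3, hp.eps1, alpha,
                                   "down", w, b)
            assert after <= before + 1e-12
            alpha = update_alpha(w)

    def test_sparse_recovery_with_lasso_term(self, rng):
        # only marker 0 is causal; the reweighted L1 term should suppress
        # the other weights relative to an unregularized fit
        X = rng.normal(size=(50, 10))
        y = 2.0 * X[:, 0] + 0.3 * rng.normal(size=50)
        res = fit_ilstsvr(X, y, ILSTSVRHyperparams(C1=1.0, C3=1.0))
        w = np.abs(0.5 * (res.w1 + res.w2))
        assert w[1:].max() < 0.1 * w[0]

    def test_permutation_equivariance(self, small_xy, rng):
        X, y = small_xy
        hp = ILSTSVRHyperparams(C1=2.0, C3=0.5)
        perm = rng.permutation(len(y))
        Xnew = rng.normal(size=(5, X.shape[1]))
        p1 = fit_ilstsvr(X, y, hp).predict(Xnew)
        p2 = fit_ilstsvr(X[perm], y[perm], hp).predict(Xnew)
        np.testing.assert_allclose(p1, p2, rtol=1e-8)

    def test_kernel_permutation_equivariance(self, rng):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        hp = ILSTSVRHyperparams(C1=2.0, C3=0.5, kernel="rbf", sigma=1.5)
        perm = rng.permutation(15)
        Xnew = rng.normal(size=(4, 3))
        p1 = fit_ilstsvr(X, y, hp).predict(Xnew)
        p2 = fit_ilstsvr(X[perm], y[perm], hp).predict(Xnew)
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_constant_phenotype_collapses_to_bias(self, rng):
        # with the Lasso term off, the fit is exactly the constant; with it
        # on, the regularized bias shrinks slightly toward zero
        X = rng.normal(size=(10, 3))
        res0 = fit_ilstsvr(X, np.full(10, 3.5),
                           ILSTSVRHyperparams(C1=1.0, C3=0.0, eps1=0, eps2=0))
        np.testing.assert_allclose(res0.predict(X), 3.5, atol=1e-8)
        res = fit_ilstsvr(X, np.full(10, 3.5),
                          ILSTSVRHyperparams(C1=1.0, C3=0.1, eps1=0, eps2=0))
        pred = res.predict(X)
        assert np.ptp(pred) < 1e-6 and abs(pred[0] - 3.5) < 0.05

    def test_misaligned_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            ILSTSVR(np.zeros(5), rng.normal(size=(4, 2)))


class TestPrediction:
    def test_linear_prediction_formula(self):
        from twingp.model import TwinRegressionResults
        model = ILSTSVR(np.zeros(2), [[3.0], [0.0]],
                        ILSTSVRHyperparams(C1=1.0))
        res = TwinRegressionResults(model, np.array([2.0]), 0.0,
                                    np.array([2.0]), 0.0, np.ones(1),
                                    np.ones(1), 1, True)
        assert res.predict([[3.0], [1.0]])[0] == pytest.approx(6.0)
        res2 = TwinRegressionResults(model, np.array([1.0]), 0.0,
                                     np.array([3.0]), 2.0, np.ones(1),
                                     np.ones(1), 1, True)
        assert res2.predict([[1.0], [0.0]])[0] == pytest.approx(3.0)

    def test_kernel_model_noiseless_fit(self, rng):
        X = rng.uniform(0, 2, size=(40, 2))
        y = np.sin(2 * X[:, 0]) + X[:, 1] ** 2
        hp = ILSTSVRHyperparams(C1=100.0, C3=1e-3, eps1=0, eps2=0,
                                kernel="rbf", sigma=0.7)
        res = ILSTSVR(y, X, hp).fit()
        assert np.mean((res.predict(X) - y) ** 2) < 1e-2

    def test_marker_count_mismatch(self, small_xy):
        X, y = small_xy
        res = fit_lstsvr(X, y, ILSTSVRHyperparams(C1=1.0))
        with pytest.raises(ValueError):
            res.predict(np.zeros((2, X.shape[1] + 1)))

    def test_summary_mentions_fit(self, small_xy):
        X, y = small_xy
        res = fit_ilstsvr(X, y, ILSTSVRHyperparams(C1=1.0, C3=0.5))
        text = res.summary()
        assert "Twin Support Vector Regression" in text
        assert "converged" in text

    def test_from_dataframe_inner_joins(self):
        import pandas as pd
        g = pd.DataFrame(np.eye(4), index=list("abcd"),
                         columns=[f"m{i}" for i in range(4)])
        p = pd.DataFrame({"trait": [1.0, 2.0, 3.0]}, index=list("cab"))
        m = ILSTSVR.from_dataframe(g, p, trait="trait", C1=1.0)
        assert m.exog.sample_ids == ["a", "b", "c"]
        np.testing.assert_allclose(m.endog.values, [2.0, 3.0, 1.0])
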