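"""Shrinkage operators, ISTA solvers and cross-validated lambda selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from cspdecode import (
    ColumnStandardizer,
    SolverConfig,
    SparseProblem,
    cv_select_lambda,
    default_lambda_grid,
    ista_lasso,
    ista_log,
    prox_log,
    soft_threshold,
)
from cspdecode.sparse import spectral_step_constant
from cspdecode.errors import DataError

A_DEFAULT = 0.001


def brute_force_prox_log(v, t, a, n_grid=4001):
    """Independent scalar oracle: dense grid on [0, |v|] + local refinement."""
    u = abs(v)

    def obj(x):
        return t * np.log1p(x / a) + 0.5 * (x - u) ** 2

    xs = np.linspace(0.0, u, n_grid)
    vals = obj(xs)
    i = int(np.argmin(vals))
    lo = xs[max(i - 1, 0)]
    hi = xs[min(i + 1, n_grid - 1)]
    if hi > lo:
        res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        best_x, best_v = res.x, res.fun
        if vals[i] < best_v:
            best_x, best_v = xs[i], vals[i]
    else:
        best_x, best_v = xs[i], vals[i]
    if obj(0.0) <= best_v:
        best_x = 0.0
    return np.sign(v) * best_x


class TestSoftThreshold:
    def test_examples(self):
        assert soft_threshold(np.array([2.0]), 0.5)[0] == 1.5
        assert soft_threshold(np.array([0.3, -0.2]), 0.5).tolist() == [0.0, 0.0]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=20),
        st.floats(0, 10),
    )
    def test_matches_definition(self, values, t):
        v = np.array(values)
        expected = np.array([np.sign(x) * max(abs(x) - t, 0.0) for x in values])
        np.testing.assert_array_equal(soft_threshold(v, t), expected)

    def test_negative_threshold_rejected(self):
        with pytest.raises(DataError):
            soft_threshold(np.array([1.0]), -0.1)


class TestProxLog:
    @pytest.mark.parametrize("mode", ["closed_form", "exact"])
    def test_zero_maps_to_zero(self, mode):
        assert prox_log(np.array([0.0]), 0.1, A_DEFAULT, mode=mode)[0] == 0.0

    def test_small_input_with_active_clamp_gives_exact_zero(self):
        """For |v| < a with a|v| <= lam/gamma the closed form collapses:
        the sqrt equals a - |v| and the output is exactly 0."""
        a = A_DEFAULT
        v = np.array([0.5 * a, -0.9 * a])
        out = prox_log(v, lam_over_gamma=10 * a * a, a=a, mode="closed_form")
        np.testing.assert_array_equal(out, np.zeros(2))

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0])
    def test_exact_mode_matches_brute_force_minimizer(self, t):
        rng = np.random.default_rng(7)
        v = np.concatenate([np.linspace(-10, 10, 201), rng.uniform(-10, 10, 100)])
        ours = prox_log(v, t, A_DEFAULT, mode="exact")
        oracle = np.array([brute_force_prox_log(x, t, A_DEFAULT) for x in v])
        np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_modes_agree_above_the_clamp_boundary(self):
        """For a|v| > lam/gamma the clamp is inactive and the closed form
        equals the exact minimizer."""
        t = 0.0005  # boundary at |v| = t/a = 0.5
        v = np.linspace(1.0, 10.0, 50)
        p = prox_log(v, t, A_DEFAULT, mode="closed_form")
        e = prox_log(v, t, A_DEFAULT, mode="exact")
        np.testing.assert_allclose(p, e, atol=1e-10)

    def test_modes_differ_where_clamp_truncates_discriminant(self):
        """With a|v| < lam/gamma the closed formula returns ~|v| - a while
        the exact prox can jump to 0; both behaviours are intentional."""
        v = np.array([1.0])
        p = prox_log(v, 0.05, A_DEFAULT, mode="closed_form")
        e = prox_log(v, 0.05, A_DEFAULT, mode="exact")
        assert p[0] == pytest.approx(1.0 - A_DEFAULT, abs=1e-12)
        assert e[0] < p[0]

    def test_large_a_limit_reduces_to_soft_thresholding(self):
        """log(1 + |w|/a) ~ |w|/a for large a, so the prox tends to the l1
        shrinkage with threshold (lam/gamma)/a."""
        a = 1e4
        v = np.linspace(-5, 5, 101)
        t = 2.0
        np.testing.assert_allclose(
            prox_log(v, t, a, mode="exact"),
            soft_threshold(v, t / a),
            atol=1e-6,
        )

    def test_odd_symmetry(self):
        v = np.linspace(0.01, 5, 50)
        for mode in ("closed_form", "exact"):
            np.testing.assert_allclose(
                prox_log(-v, 0.1, A_DEFAULT, mode=mode),
                -prox_log(v, 0.1, A_DEFAULT, mode=mode),
                atol=1e-12,
            )


class TestIstaLasso:
    def test_zero_targets_give_zero_weights(self, rng):
        x = rng.standard_normal((30, 10))
        prob = SparseProblem(X=x, y=np.zeros(30), lam=0.1)
        wv = ista_lasso(prob)
        assert np.all(wv.w == 0.0)
        assert wv.converged

    def test_null_solution_above_critical_lambda(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.standard_normal((25, 8))
            y = r.standard_normal(25)
            lam = np.abs(x.T @ y).max() * 1.001
            wv = ista_lasso(SparseProblem(X=x, y=y, lam=lam))
            assert np.all(wv.w == 0.0)

    def test_orthonormal_design_closed_form(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            q = np.linalg.qr(r.standard_normal((40, 15)))[0]
            y = r.standard_normal(40)
            lam = 0.3
            wv = ista_lasso(SparseProblem(X=q, y=y, lam=lam))
            np.testing.assert_allclose(wv.w, soft_threshold(q.T @ y, lam), atol=1e-8)

    def test_objective_nonincreasing(self, rng):
        x = rng.standard_normal((40, 20))
        y = rng.standard_normal(40)
        wv = ista_lasso(SparseProblem(X=x, y=y, lam=0.5))
        diffs = np.diff(wv.objective_trace)
        assert np.all(diffs <= 1e-12)


class TestIstaLog:
    def test_zero_targets_fixed_point_in_one_iteration(self, rng):
        x = rng.standard_normal((30, 10))
        prob = SparseProblem(X=x, y=np.zeros(30), lam=0.1)
        wv = ista_log(prob)
        assert np.all(wv.w == 0.0)
        assert wv.iterations == 1

    def test_identity_design_fixed_point_is_prox_of_y(self, rng):
        n = 12
        y = rng.standard_normal(n) * 2
        prob = SparseProblem(X=np.eye(n), y=y, lam=0.2)
        wv = ista_log(prob, SolverConfig(tol=1e-10))
        expected = prox_log(y, 0.2 / prob.gamma, prob.a, mode="closed_form")
        np.testing.assert_allclose(wv.w, expected, atol=1e-8)
        assert prob.gamma == pytest.approx(1.0)

    def test_exact_mode_objective_nonincreasing_many_instances(self):
        """Majorization descent: each prox-gradient step cannot increase the
        separable objective when the prox is exact."""
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = r.standard_normal((20, 8))
            y = r.standard_normal(20)
            prob = SparseProblem(X=x, y=y, lam=float(r.uniform(0.05, 2.0)))
            wv = ista_log(prob, SolverConfig(mode="exact", max_iter=300))
            assert np.all(np.diff(wv.objective_trace) <= 1e-12)

    def test_closed_form_mode_converges_on_well_conditioned_problems(self):
        """10/10 seeds reach the relative-change tolerance on N=100, P=60
        problems with strong signal."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.standard_normal((100, 60))
            w_true = np.zeros(60)
            w_true[:3] = [2.0, -1.5, 1.0]
            y = x @ w_true + 0.1 * r.standard_normal(100)
            wv = ista_log(SparseProblem(X=x, y=y, lam=1.0), SolverConfig())
            assert wv.converged

    def test_solution_is_local_minimum_under_random_probes(self, rng):
        x = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        prob = SparseProblem(X=x, y=y, lam=0.5)
        wv = ista_log(prob, SolverConfig(mode="exact", tol=1e-12, max_iter=5000))

        def objective(w):
            r_ = y - x @ w
            return 0.5 * r_ @ r_ + 0.5 * np.sum(np.log1p(np.abs(w) / prob.a))

        base = objective(wv.w)
        probes = wv.w + 1e-4 * rng.standard_normal((10000, 5))
        probe_objs = np.array([objective(p) for p in probes])
        assert base <= probe_objs.min() + 1e-9

    def test_column_permutation_equivariance(self, rng):
        x = rng.standard_normal((30, 8))
        y = rng.standard_normal(30)
        perm = rng.permutation(8)
        w1 = ista_log(SparseProblem(X=x, y=y, lam=0.3)).w
        w2 = ista_log(SparseProblem(X=x[:, perm], y=y, lam=0.3)).w
        np.testing.assert_allclose(w2, w1[perm], atol=1e-10)

    def test_nonconvergence_reported_not_raised(self, rng):
        x = rng.standard_normal((30, 10))
        y = rng.standard_normal(30)
        wv = ista_log(SparseProblem(X=x, y=y, lam=0.01), SolverConfig(max_iter=2, tol=1e-15))
        assert not wv.converged


class TestStepConstant:
    def test_power_iteration_matches_dense_norm(self, rng):
        x = rng.standard_normal((30, 12))
        assert spectral_step_constant(x) == pytest.approx(
            np.linalg.norm(x, 2) ** 2, rel=1e-8
        )


class TestStandardizer:
    def test_zero_mean_unit_variance_and_constant_passthrough(self, rng):
        x = rng.standard_normal((50, 4)) * [1, 10, 0.1, 1] + [5, -3, 0, 0]
        x[:, 3] = 2.0  # constant column
        z = ColumnStandardizer().fit_transform(x)
        np.testing.assert_allclose(z[:, :3].mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z[:, :3].std(axis=0), 1, atol=1e-12)
        np.testing.assert_allclose(z[:, 3], 0, atol=1e-12)


class TestCvSelectLambda:
    def test_grid_has_51_points_spanning_2pow_pm5(self):
        grid = default_lambda_grid()
        assert grid.size == 51
        assert grid[0] == pytest.approx(2.0**-5)
        assert grid[-1] == pytest.approx(2.0**5)
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, 2.0**0.2, rtol=1e-10)

    def test_recovers_informative_features(self):
        """3 informative of 60 columns: the support at lambda* contains all
        three in at least 8 of 10 seeds."""
        hits = 0
        grid = default_lambda_grid()[::5]  # coarse sweep of the same range
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 60
            y = np.resize([1.0, -1.0], n)
            x = 0.5 * r.standard_normal((n, 60))
            x[:, :3] += np.outer(y, [2.0, -2.0, 1.5])
            lam_star, _ = cv_select_lambda(
                x, y, selector="log", folds=10, grid=grid, seed=seed
            )
            from cspdecode import ista_log

            wv = ista_log(SparseProblem(X=x, y=y, lam=lam_star))
            if set(range(3)) <= set(wv.support().tolist()):
                hits += 1
        assert hits >= 8

    def test_constant_features_handled_deterministically(self):
        x = np.ones((40, 5))
        y = np.resize([1.0, -1.0], 40)
        grid = np.array([0.5, 1.0, 2.0])
        lam1, table = cv_select_lambda(x, y, selector="lasso", grid=grid, seed=0)
        lam2, _ = cv_select_lambda(x, y, selector="lasso", grid=grid, seed=0)
        assert lam1 == lam2  # ties broken deterministically toward larger lambda
        assert list(table.columns) == ["lambda", "mean_score", "mean_support"]

    def test_too_few_samples_rejected(self, rng):
        x = rng.standard_normal((5, 3))
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        with pytest.raises(DataError):
            cv_select_lambda(x, y, folds=10)
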