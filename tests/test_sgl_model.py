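import numpy as np
import pytest

from kmerlasso.sgl_model import (
    cross_validate,
    default_lambda_grids,
    fit,
    fit_multitask,
    kkt_residual,
    lambda_max,
    objective,
    prox_sgl,
)

from conftest import make_groups, make_matrix
from oracles import (
    logistic_loss_direct,
    min_unpenalized_logistic,
    prox_argmin_numeric,
    random_sgl_instance,
)


class TestObjective:
    def test_zero_weights_give_n_log2(self):
        rng = np.random.default_rng(0)
        X, y, gof = random_sgl_instance(rng, n=20, p=6, G=2)
        M, A = make_matrix(X, y), make_groups(gof)
        assert objective(np.zeros(6), M, A, 1.0, 1.0) == pytest.approx(20 * np.log(2))

    def test_unpenalized_equals_direct_summation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 4))
        y = np.array([1, -1, 1, -1, 1])
        w = rng.normal(size=4)
        M, A = make_matrix(X, y), make_groups([1, 1, 2, 2])
        assert objective(w, M, A, 0.0, 0.0) == pytest.approx(
            logistic_loss_direct(w, X, y), rel=1e-12)

    def test_printed_group_penalty_with_lg_weight(self):
        """lambda1 * l_g * ||w_g|| at exponent 1: l_g=2, w=(3,4) -> 10."""
        X = np.zeros((2, 2))
        y = np.array([1, -1])
        M, A = make_matrix(X, y), make_groups([1, 1])
        val = objective(np.array([3.0, 4.0]), M, A, 1.0, 0.0,
                        group_weight_exponent=1.0)
        assert val == pytest.approx(2 * np.log(2) + 10.0)

    def test_nonfinite_weights_rejected(self):
        M, A = make_matrix(np.zeros((2, 2)), [1, -1]), make_groups([1, 2])
        with pytest.raises(ValueError):
            objective(np.array([np.inf, 0.0]), M, A, 0.0, 0.0)


class TestProx:
    def test_origin_is_fixed(self):
        A = make_groups([1, 1, 2])
        assert (prox_sgl(np.zeros(3), A, 0.5, 0.5) == 0).all()

    def test_small_group_norm_zeroes_block(self):
        A = make_groups([1, 1])
        v = np.array([0.1, -0.1])
        out = prox_sgl(v, A, tlam1=10.0, tlam2=0.0)
        assert (out == 0.0).all()

    def test_matches_numeric_argmin_sample(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = int(rng.integers(4, 12))
            G = int(rng.integers(1, p + 1))
            gof = np.concatenate([np.arange(1, G + 1), rng.integers(1, G + 1, p - G)])
            rng.shuffle(gof)
            A = make_groups(gof)
            v = rng.normal(0, 2, p)
            t, l1, l2 = rng.uniform(0.1, 2), rng.uniform(0, 1), rng.uniform(0, 1)
            ours = prox_sgl(v, A, t * l1, t * l2)
            ref = prox_argmin_numeric(v, gof, A.G, t * l1, t * l2)
            assert np.abs(ours - ref).max() < 1e-6

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            prox_sgl(np.zeros(3), make_groups([1, 2]), 0.1, 0.1)


class TestFit:
    def test_above_lambda_max_is_exactly_zero(self):
        rng = np.random.default_rng(3)
        X, y, gof = random_sgl_instance(rng)
        M, A = make_matrix(X, y), make_groups(gof)
        l1m, l2m = lambda_max(M, A)
        res = fit(M, A, l1m * 1.001, l2m * 1.001)
        assert (res.w == 0.0).all()
        assert res.objective_trace[-1] == pytest.approx(len(y) * np.log(2))

    def test_unregularized_matches_logistic_oracle(self):
        # n >> p so the problem is not separable
        rng = np.random.default_rng(4)
        n, p = 200, 6
        X = rng.poisson(1.0, (n, p)).astype(float)
        w_true = rng.normal(0, 0.5, p)
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-(X @ w_true))), 1, -1)
        M, A = make_matrix(X, y), make_groups([1, 1, 2, 2, 3, 3])
        res = fit(M, A, 0.0, 0.0, tol=0.0, max_iter=20000)
        assert res.objective_trace[-1] == pytest.approx(
            min_unpenalized_logistic(X, y), rel=1e-5)

    def test_trace_monotone_and_zero_blocks_exact(self):
        rng = np.random.default_rng(5)
        X, y, gof = random_sgl_instance(rng)
        M, A = make_matrix(X, y), make_groups(gof)
        res = fit(M, A, 0.3, 0.1)
        assert (np.diff(res.objective_trace) <= 1e-10).all()
        for g in range(1, A.G + 1):
            wg = res.w[A.members(g)]
            assert (wg == 0.0).all() or np.any(wg != 0.0)

    def test_kkt_residual_small_at_tight_tolerance(self):
        rng = np.random.default_rng(6)
        X, y, gof = random_sgl_instance(rng)
        M, A = make_matrix(X, y), make_groups(gof)
        res = fit(M, A, 0.1, 0.1, tol=0.0, max_iter=30000)
        assert kkt_residual(res, M) < 1e-4

    def test_invariant_to_group_relabeling_and_feature_permutation(self):
        rng = np.random.default_rng(7)
        X, y, gof = random_sgl_instance(rng)
        M, A = make_matrix(X, y), make_groups(gof)
        res = fit(M, A, 0.2, 0.05, tol=1e-10, max_iter=10000)
        perm = rng.permutation(X.shape[1])
        relabel = rng.permutation(A.G) + 1
        M2 = make_matrix(X[:, perm], y)
        A2 = make_groups(relabel[gof[perm] - 1])
        res2 = fit(M2, A2, 0.2, 0.05, tol=1e-10, max_iter=10000)
        assert np.allclose(res2.w, res.w[perm], atol=1e-6)

    def test_both_classes_required(self):
        M = make_matrix(np.ones((4, 2)), [1, 1, 1, 1])
        with pytest.raises(ValueError):
            fit(M, make_groups([1, 2]), 0.1, 0.1)


class TestCrossValidate:
    def data(self, seed, n=80, p=8, signal=0.0):
        rng = np.random.default_rng(seed)
        X = rng.poisson(1.0, (n, p)).astype(float)
        y = np.where(rng.random(n) < 0.5, 1, -1)
        if signal:
            X[y > 0, 0] += rng.poisson(signal, (y > 0).sum())
        return make_matrix(X, y), make_groups([1 + i % 3 for i in range(p)])

    def test_single_grid_point_trivial(self):
        M, A = self.data(0)
        l1, l2, table = cross_validate(M, A, [0.3], [0.1], folds=4, seed=0)
        assert (l1, l2) == (0.3, 0.1)
        assert len(table) == 1

    def test_pure_noise_chosen_model_near_chance_on_fresh_data(self):
        from kmerlasso.evaluation import auroc

        hits = 0
        for seed in range(10):
            M, A = self.data(100 + seed)
            Mtest, _ = self.data(200 + seed, n=200)
            l1, l2, _ = cross_validate(M, A, folds=4, seed=seed, max_iter=150)
            res = fit(M, A, l1, l2)
            au = 0.5 if not np.any(res.w) else auroc(
                res.decision_values(Mtest), Mtest.labels)
            hits += 0.4 <= au <= 0.6
        assert hits >= 9

    def test_strong_signal_yields_nonzero_weights(self):
        M, A = self.data(1, signal=3.0)
        l1, l2, _ = cross_validate(M, A, folds=4, seed=1)
        res = fit(M, A, l1, l2)
        assert np.any(res.w != 0.0)

    def test_too_few_folds_rejected(self):
        M, A = self.data(2)
        with pytest.raises(ValueError):
            cross_validate(M, A, [0.1], [0.1], folds=1)

    def test_default_grids_descend_from_lambda_max(self):
        M, A = self.data(3)
        g1, g2 = default_lambda_grids(M, A, n_points=5)
        l1m, l2m = lambda_max(M, A)
        assert g1[0] == pytest.approx(l1m) and g2[0] == pytest.approx(l2m)
        assert (np.diff(g1) < 0).all() and (np.diff(g2) < 0).all()


class TestMultitask:
    def stacked_data(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 60, 6
        X = rng.poisson(1.0, (2 * n, p)).astype(float)
        y = np.where(rng.random(2 * n) < 0.5, 1, -1)
        y[:2] = [1, -1]
        y[n:n + 2] = [1, -1]
        tasks = ["T1"] * n + ["T2"] * n
        M = make_matrix(X, y, tasks=tasks)
        A = make_groups([1, 1, 2, 2, 3, 3])
        return M, {"T1": A, "T2": A}, A

    def test_requires_task_ids_and_two_tasks(self):
        rng = np.random.default_rng(8)
        X, y, gof = random_sgl_instance(rng, n=20, p=6, G=3)
        M, A = make_matrix(X, y), make_groups(gof)
        with pytest.raises(ValueError):
            fit_multitask(M, {"T1": A}, A, 0.1, 0.1)

    def test_identical_tasks_concentrate_in_common_block(self):
        """With alpha >> beta duplicated data drives signal into w_c."""
        rng = np.random.default_rng(9)
        n, p = 60, 6
        X1 = rng.poisson(1.0, (n, p)).astype(float)
        y1 = np.where(rng.random(n) < 0.5, 1, -1)
        X1[y1 > 0, 0] += 2.0
        X = np.vstack([X1, X1])
        y = np.concatenate([y1, y1])
        M = make_matrix(X, y, tasks=["T1"] * n + ["T2"] * n)
        A = make_groups([1, 1, 2, 2, 3, 3])
        mt = fit_multitask(M, {"T1": A, "T2": A}, A, 0.05, 0.01,
                           alpha=10.0, beta=1.0)
        total_task = sum(np.abs(w).sum() for w in mt.w_task.values())
        assert np.abs(mt.w_common).sum() > 0.0
        assert total_task < 0.1 * np.abs(mt.w_common).sum()

    def test_prediction_uses_sum_of_blocks(self):
        M, per_task, common = self.stacked_data(10)
        mt = fit_multitask(M, per_task, common, 0.05, 0.01)
        z = mt.decision_values(M, "T1")
        manual = M.counts @ (mt.w_common + mt.w_task["T1"])
        assert np.allclose(z, np.asarray(manual).ravel())
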