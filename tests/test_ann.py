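"""MLP forward/Jacobian/LM correctness against independent oracles."""

import math

import numpy as np
import pytest

from kinotox import ann
from kinotox.errors import InvalidArgumentError


def _bare_linear(w, b):
    """1-input linear net without input/output scaling."""
    return ann.MLPNetwork([np.array([[float(w)]])], [np.array([float(b)])], ["purelin"])


class TestForward:
    def test_identity_linear_net(self):
        net = _bare_linear(1.0, 0.0)
        x = np.array([[0.3], [-2.0]])
        np.testing.assert_allclose(ann.forward(net, x), [0.3, -2.0])

    def test_zero_weights_return_bias(self):
        net = _bare_linear(0.0, 4.5)
        np.testing.assert_allclose(ann.forward(net, [[1.0], [99.0]]), [4.5, 4.5])

    def test_tanh_hidden_zero_input_zero_output(self):
        net = ann.init_network([2, 3, 1], seed=0)
        for b in net.biases:
            b[:] = 0.0
        out = ann.forward(net, [[0.0, 0.0]])
        assert out[0] == pytest.approx(0.0)

    def test_dimension_mismatch_rejected(self):
        net = ann.init_network([3, 2, 1], seed=0)
        with pytest.raises(InvalidArgumentError):
            ann.forward(net, [[1.0, 2.0]])


class TestJacobian:
    def test_linear_net_jacobian_rows(self):
        net = _bare_linear(2.0, 1.0)
        X = np.array([[3.0], [5.0]])
        y = np.array([0.0, 0.0])
        r, J = ann.jacobian(net, X, y)
        np.testing.assert_allclose(r, [7.0, 11.0])
        np.testing.assert_allclose(J, [[3.0, 1.0], [5.0, 1.0]])

    def test_zero_error_batch_zero_residual(self):
        net = _bare_linear(2.0, 1.0)
        X = np.array([[3.0]])
        r, J = ann.jacobian(net, X, np.array([7.0]))
        np.testing.assert_allclose(r, [0.0])
        assert J.shape == (1, 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        sizes = [3, int(rng.integers(2, 5)), int(rng.integers(2, 4)), 1]
        transfers = [str(rng.choice(["tansig", "logsig"]))] * 2 + ["purelin"]
        net = ann.init_network(sizes, transfers, seed=seed)
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        r, J = ann.jacobian(net, X, y)
        theta = ann._pack(net)
        eps = 1e-6
        J_fd = np.empty_like(J)
        for k in range(len(theta)):
            tp = theta.copy()
            tp[k] += eps
            ann._unpack(net, tp)
            r_plus, _ = ann.jacobian(net, X, y)
            tm = theta.copy()
            tm[k] -= eps
            ann._unpack(net, tm)
            r_minus, _ = ann.jacobian(net, X, y)
            J_fd[:, k] = (r_plus - r_minus) / (2 * eps)
        ann._unpack(net, theta)
        np.testing.assert_allclose(J, J_fd, rtol=1e-5, atol=1e-8)


class TestTrainLM:
    def test_fits_exact_linear_map(self):
        X = np.linspace(-2, 2, 20).reshape(-1, 1)
        y = 0.5 * X[:, 0]
        net = ann.init_network([1, 1], ["purelin"], seed=1)
        res = ann.train_lm(net, X, y)
        assert res.train_rmse <= 1e-8
        np.testing.assert_allclose(ann.forward(net, X), y, atol=1e-7)

    def test_linear_net_equals_least_squares(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 4))
        y = X @ [1.0, -2.0, 0.5, 3.0] + 0.2 + rng.normal(0, 0.3, 60)
        net = ann.init_network([4, 1], ["purelin"], seed=2)
        ann.train_lm(net, X, y, ann.LMConfig(min_gradient=1e-12))
        A = np.column_stack([X, np.ones(len(y))])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(ann.forward(net, X), A @ beta, atol=1e-8)

    def test_accepted_rmse_strictly_decreasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 2))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
        net = ann.init_network([2, 5, 1], seed=3)
        res = ann.train_lm(net, X, y, ann.LMConfig(max_epochs=50))
        diffs = np.diff(res.rmse_curve)
        assert np.all(diffs < 0)

    def test_xor_is_solved(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0.0, 1.0, 1.0, 0.0])
        best = math.inf
        for seed in range(5):
            net = ann.init_network([2, 2, 1], seed=seed)
            res = ann.train_lm(net, X, y)
            best = min(best, res.train_rmse)
        assert best < 0.05

    def test_empty_data_rejected(self):
        net = ann.init_network([2, 1], ["purelin"], seed=0)
        with pytest.raises(InvalidArgumentError):
            ann.train_lm(net, np.empty((0, 2)), np.empty(0))


class TestSplit:
    @pytest.mark.parametrize("n,frac,n_train", [(1000, 0.9, 900), (10, 0.9, 9), (5, 0.5, 2)])
    def test_sizes(self, n, frac, n_train):
        tr, te = ann.split_indices(n, frac, seed=0)
        assert len(tr) == n_train
        assert len(te) == n - n_train

    def test_partition_is_disjoint_and_complete(self):
        tr, te = ann.split_indices(100, 0.9, seed=1)
        assert set(tr).isdisjoint(te)
        assert set(tr) | set(te) == set(range(100))

    def test_deterministic_under_seed(self):
        a = ann.split_indices(50, 0.9, seed=4)
        b = ann.split_indices(50, 0.9, seed=4)
        np.testing.assert_array_equal(a[0], b[0])
        c = ann.split_indices(50, 0.9, seed=5)
        assert not np.array_equal(a[0], c[0])

    def test_too_small_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ann.split_indices(1, 0.9, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ann.split_indices(10, 1.0, seed=0)


class TestEvaluate:
    def test_perfect_predictions(self):
        net = _bare_linear(1.0, 0.0)
        X = np.array([[1.0], [2.0], [3.0]])
        rmse, r2 = ann.evaluate(net, X, np.array([1.0, 2.0, 3.0]))
        assert rmse == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_constant_predictions_undefined_r2(self):
        net = _bare_linear(0.0, 2.0)  # predicts mean of y
        y = np.array([1.0, 2.0, 3.0])
        rmse, r2 = ann.evaluate(net, np.ones((3, 1)), y)
        assert math.isnan(r2)
        assert rmse == pytest.approx(np.std(y))

    def test_hand_computed_four_points(self):
        net = _bare_linear(1.0, 0.0)
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([1.1, 1.9, 3.2, 3.9])
        rmse, r2 = ann.evaluate(net, X, y)
        resid = X[:, 0] - y
        assert rmse == pytest.approx(float(np.sqrt(np.mean(resid**2))))
        assert r2 == pytest.approx(float(np.corrcoef(X[:, 0], y)[0, 1]) ** 2)


class TestArchitectureSearch:
    def _teacher_data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        teacher = ann.init_network([2, 4, 1], seed=11, init_range=1.5)
        X = rng.uniform(-2, 2, size=(n, 2))
        y = ann.forward(teacher, X) + rng.normal(0, 0.02, n)
        return X, y

    def test_selects_nonlinear_teacher_over_linear(self):
        X, y = self._teacher_data()
        candidates = [((), ()), ((4,), ("tansig",))]
        ranked = ann.architecture_search(
            X, y, candidates, ann.LMConfig(max_epochs=200), seed=1, n_restarts=3
        )
        assert ranked[0].network.layer_sizes == (2, 4, 1)

    def test_single_candidate_rank_one(self):
        X, y = self._teacher_data(n=60)
        ranked = ann.architecture_search(
            X, y, [((3,), ("tansig",))], ann.LMConfig(max_epochs=50), seed=2, n_restarts=1
        )
        assert len(ranked) == 1

    def test_identical_candidates_identical_metrics(self):
        X, y = self._teacher_data(n=60)
        cand = ((3,), ("tansig",))
        r1 = ann.architecture_search(X, y, [cand], ann.LMConfig(max_epochs=50), seed=3, n_restarts=1)
        r2 = ann.architecture_search(X, y, [cand], ann.LMConfig(max_epochs=50), seed=3, n_restarts=1)
        assert r1[0].test_rmse == r2[0].test_rmse
        assert r1[0].test_r2 == r2[0].test_r2

    def test_empty_grid_rejected(self):
        X, y = self._teacher_data(n=20)
        with pytest.raises(InvalidArgumentError):
            ann.architecture_search(X, y, [])

    def test_ranking_order_r2_desc_then_rmse(self):
        X, y = self._teacher_data(n=120, seed=5)
        ranked = ann.architecture_search(
            X,
            y,
            [((2,), ("tansig",)), ((4,), ("tansig",)), ((6,), ("logsig",))],
            ann.LMConfig(max_epochs=100),
            seed=4,
            n_restarts=2,
        )
        r2s = [r.test_r2 for r in ranked if math.isfinite(r.test_r2)]
        assert r2s == sorted(r2s, reverse=True)
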