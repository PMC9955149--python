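import numpy as np
import pytest

from diacascade import (
    TrainConfig,
    forward,
    gradient,
    hidden_preset,
    init_mlp,
    train_noprop,
    train_scg,
)
from diacascade.errors import InputError, ParameterError, TrainingError
from diacascade.neural import _flatten, _unflatten, mse


class TestForward:
    def test_zero_weights_sigmoid_gives_half(self):
        m = init_mlp([3, 4, 2], seed=0)
        for w in m.weights:
            w[...] = 0.0
        for b in m.biases:
            b[...] = 0.0
        np.testing.assert_allclose(forward(m, np.zeros(3)), [0.5, 0.5])

    def test_hand_computed_1_1_1_network(self):
        m = init_mlp([1, 1, 1], seed=0)
        m.weights[0][...] = 2.0
        m.biases[0][...] = -1.0
        m.weights[1][...] = 1.0
        m.biases[1][...] = 0.5
        x = 0.75
        h = 1 / (1 + np.exp(-(2 * x - 1)))
        expected = 1 / (1 + np.exp(-(h + 0.5)))
        assert forward(m, np.array([x]))[0] == pytest.approx(expected, rel=1e-12)

    def test_hidden_unit_permutation_equivariance(self):
        m = init_mlp([3, 5, 2], seed=1)
        x = np.random.default_rng(0).normal(size=3)
        base = forward(m, x)
        perm = np.array([2, 0, 4, 1, 3])
        m.weights[0] = m.weights[0][:, perm]
        m.biases[0] = m.biases[0][perm]
        m.weights[1] = m.weights[1][perm, :]
        np.testing.assert_allclose(forward(m, x), base, rtol=1e-12)

    def test_dimension_mismatch_names_widths(self):
        m = init_mlp([3, 2], seed=0)
        with pytest.raises(InputError, match="expected 3"):
            forward(m, np.zeros(4))


class TestGradient:
    @pytest.mark.parametrize(
        "sizes,hidden_act,out_act",
        [([3, 4, 2], "sigmoid", "sigmoid"), ([2, 5, 3, 2], "tanh", "sigmoid"),
         ([4, 3, 1], "sigmoid", "linear")],
    )
    def test_backprop_matches_central_differences(self, sizes, hidden_act, out_act):
        rng = np.random.default_rng(12)
        m = init_mlp(sizes, seed=3, hidden_activation=hidden_act, output_activation=out_act)
        X = rng.normal(size=(7, sizes[0]))
        Y = rng.uniform(size=(7, sizes[-1]))
        g = gradient(m, X, Y)
        theta = _flatten(m)
        h = 1e-6
        num = np.empty_like(theta)
        for i in range(theta.size):
            up, dn = theta.copy(), theta.copy()
            up[i] += h
            dn[i] -= h
            _unflatten(m, up)
            fu = mse(m, X, Y)
            _unflatten(m, dn)
            fd = mse(m, X, Y)
            num[i] = (fu - fd) / (2 * h)
        _unflatten(m, theta)
        rel = np.abs(g - num) / (np.abs(num) + 1e-8)
        assert rel.max() <= 1e-5


class TestTrainSCG:
    def test_convex_quadratic_reaches_least_squares_optimum(self):
        # linear 1-in 1-out net on a line fit: MSE is a convex quadratic
        X = np.array([[1.0], [2.0], [3.0]])
        Y = np.array([[2.0], [3.9], [6.1]])
        m = init_mlp([1, 1], seed=0, output_activation="linear")
        m = train_scg(m, X, Y, TrainConfig(max_epochs=50, goal_mse=0.0, seed=0))
        A = np.hstack([X, np.ones((3, 1))])
        w_ls, *_ = np.linalg.lstsq(A, Y, rcond=None)
        opt_mse = float(np.mean((A @ w_ls - Y) ** 2))
        assert m.trace[-1] <= opt_mse + 1e-8
        assert m.weights[0][0, 0] == pytest.approx(w_ls[0, 0], abs=1e-5)
        assert m.biases[0][0] == pytest.approx(w_ls[1, 0], abs=1e-5)

    def test_xor_separates(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        Y = np.array([[1, 0], [0, 1], [0, 1], [1, 0]], dtype=float)
        best = np.inf
        for seed in (0, 1, 2):  # deterministic multi-start
            m = init_mlp([2, 4, 2], seed=seed)
            m = train_scg(
                m, X, Y, TrainConfig(max_epochs=500, goal_mse=1e-3, seed=seed, patience=100)
            )
            best = min(best, m.trace[-1])
            if best < 0.01:
                break
        assert best < 0.01

    def test_trace_non_increasing(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        Y = rng.uniform(size=(20, 2))
        m = train_scg(init_mlp([3, 6, 2], seed=2), X, Y, TrainConfig(max_epochs=80, seed=2))
        assert all(b <= a + 1e-15 for a, b in zip(m.trace, m.trace[1:]))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 2))
        Y = rng.uniform(size=(15, 2))
        runs = []
        for _ in range(2):
            m = train_scg(init_mlp([2, 3, 2], seed=4), X, Y, TrainConfig(seed=4, max_epochs=30))
            runs.append(_flatten(m))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_non_finite_inputs_rejected(self):
        m = init_mlp([2, 2], seed=0)
        X = np.array([[1.0, np.nan]])
        with pytest.raises(InputError):
            train_scg(m, X, np.array([[1.0, 0.0]]), TrainConfig())


class TestTrainNoProp:
    def _blobs(self, seed=0, sep=4.0, n=60):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))])
        Y = np.repeat([[1, 0], [0, 1]], n, axis=0).astype(float)
        return X, Y

    def test_separable_blobs_high_training_accuracy(self):
        X, Y = self._blobs()
        m = train_noprop(init_mlp([2, 20, 2], seed=1), X, Y, TrainConfig(seed=1))
        pred = forward(m, X).argmax(axis=1)
        assert (pred == Y.argmax(axis=1)).mean() >= 0.95

    def test_hidden_weights_frozen(self):
        X, Y = self._blobs()
        m0 = init_mlp([2, 10, 2], seed=3)
        m = train_noprop(m0, X, Y, TrainConfig(seed=3))
        np.testing.assert_array_equal(m.weights[0], m0.weights[0])

    def test_huge_ridge_drives_outputs_constant(self):
        X, Y = self._blobs()
        m = train_noprop(
            init_mlp([2, 10, 2], seed=1), X, Y, TrainConfig(seed=1, ridge=1e12)
        )
        out = forward(m, X)
        assert np.abs(m.weights[-1]).max() < 1e-6
        assert np.ptp(out, axis=0).max() < 1e-6

    def test_singular_without_ridge_advises_ridge(self):
        # duplicated hidden unit makes the normal equations singular
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        m = init_mlp([2, 2, 2], seed=0)
        m.weights[0][:, 1] = m.weights[0][:, 0]
        m.biases[0][1] = m.biases[0][0]
        with pytest.raises(TrainingError, match="ridge"):
            train_noprop(m, X, Y, TrainConfig(ridge=0.0))

    def test_same_seed_bit_identical(self):
        X, Y = self._blobs()
        a = train_noprop(init_mlp([2, 8, 2], seed=9), X, Y, TrainConfig(seed=9))
        b = train_noprop(init_mlp([2, 8, 2], seed=9), X, Y, TrainConfig(seed=9))
        np.testing.assert_array_equal(_flatten(a), _flatten(b))


class TestConfiguration:
    def test_deep_preset_has_five_hidden_layers(self):
        hidden = hidden_preset("deep")
        m = init_mlp([6, *hidden, 2], seed=0)
        assert m.n_hidden_layers == 5

    def test_default_preset_has_three_hidden_layers(self):
        assert hidden_preset("default") == (50, 25, 5)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ParameterError):
            TrainConfig(max_epochs=0)
        with pytest.raises(ParameterError):
            TrainConfig(sigma0=0.0)
        with pytest.raises(ParameterError):
            hidden_preset("nope")
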