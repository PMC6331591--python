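import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

from mucosim import (FitReport, MLPConfig, NeuralNet, TrainingError,
                     evaluate_fit, lm_train, train_with_restarts)
from mucosim.neuralnet import _sigmoid, lm_step


def make_net(W1, b1, w2, b2, d):
    h = len(b1)
    return NeuralNet(x_mean=np.zeros(d), x_scale=np.ones(d),
                     y_mean=0.0, y_scale=1.0,
                     W1=np.asarray(W1, float).reshape(h, d),
                     b1=np.asarray(b1, float), w2=np.asarray(w2, float),
                     b2=float(b2))


class TestForward:
    def test_zero_weight_net_returns_bias(self):
        net = make_net(np.zeros((3, 2)), np.zeros(3), np.zeros(3), 4.5, d=2)
        for x in ([0.0, 0.0], [1.0, -7.0], [100.0, 3.0]):
            assert net.forward(np.array(x)) == pytest.approx(4.5)

    def test_hand_set_identity_on_first_feature(self):
        # linear output layer + zeroed hidden contribution realizes y = x1:
        # one neuron with tiny input weight operates in the sigmoid's linear
        # regime: w2 * sigmoid(eps*x) ~ w2/4 * eps * x + w2/2
        eps = 1e-6
        net = make_net([[eps, 0.0]], [0.0], [4.0 / eps], -2.0 / eps, d=2)
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, size=(20, 2))
        assert np.allclose(net.forward(X), X[:, 0], atol=1e-9)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        net = make_net(rng.normal(size=(5, 3)), rng.normal(size=5),
                       rng.normal(size=5), 0.3, d=3)
        x = rng.normal(size=3)
        assert net.forward(x) == net.forward(x)

    def test_feature_count_mismatch(self):
        net = make_net(np.zeros((2, 3)), np.zeros(2), np.zeros(2), 0.0, d=3)
        with pytest.raises(ValueError, match="feature-count mismatch"):
            net.forward(np.zeros(4))


class TestLMTrain:
    def test_linear_target_reaches_ols_accuracy(self):
        # y = 2x + 1 is exactly representable; compare with the
        # ordinary-least-squares oracle
        x = np.linspace(-1, 1, 50)[:, None]
        y = 2.0 * x.ravel() + 1.0
        slope, intercept = np.polyfit(x.ravel(), y, 1)
        ols_pred = slope * x.ravel() + intercept
        assert np.mean((ols_pred - y) ** 2) < 1e-20

        net, trace = lm_train(x, y, MLPConfig(max_iter=500), init_seed=0)
        assert np.mean((net.forward(x) - y) ** 2) < 1e-8

    def test_constant_target_shortcut(self):
        x = np.linspace(-1, 1, 20)[:, None]
        net, trace = lm_train(x, np.full(20, 3.25), init_seed=0)
        assert trace.stop_reason == "constant_target"
        assert np.allclose(net.forward(x), 3.25)

    def test_sine_target_with_restarts(self):
        # independent-optimizer oracle first: the architecture can represent
        # sin(pi x) at MSE < 1e-4 (generic least-squares on the same net)
        rng = np.random.default_rng(0)
        x = np.linspace(-1, 1, 100)[:, None]
        y = np.sin(np.pi * x.ravel())
        h = 10

        def residuals(w):
            W1 = w[:h].reshape(h, 1)
            b1 = w[h:2 * h]
            w2 = w[2 * h:3 * h]
            b2 = w[-1]
            a = _sigmoid(x @ W1.T + b1)
            return a @ w2 + b2 - y

        sol = least_squares(residuals, rng.uniform(-1, 1, 3 * h + 1),
                            method="lm", max_nfev=20000)
        oracle_mse = np.mean(sol.fun ** 2)
        assert oracle_mse < 1e-4

        best = np.inf
        for k in range(10):
            net, _ = lm_train(x, y, MLPConfig(max_iter=200), init_seed=k)
            best = min(best, float(np.mean((net.forward(x) - y) ** 2)))
        assert best < 1e-4

    def test_accepted_step_mse_monotone(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-1, 1, size=(40, 2))
        y = x[:, 0] ** 2 - 0.5 * x[:, 1]
        _, trace = lm_train(x, y, MLPConfig(max_iter=100), init_seed=3)
        mse = np.array(trace.mse_path)
        assert np.all(np.diff(mse) <= 0)

    @given(st.integers(min_value=0, max_value=50))
    @settings(max_examples=10, deadline=None)
    def test_mse_monotone_property(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-1, 1, size=(25, 2))
        y = np.tanh(x[:, 0]) + 0.3 * x[:, 1]
        _, trace = lm_train(x, y, MLPConfig(max_iter=30, n_hidden=4),
                            init_seed=seed)
        assert np.all(np.diff(np.array(trace.mse_path)) <= 0)

    def test_affine_target_invariance(self):
        # standardization makes training invariant to affine rescaling of
        # the target for fixed seeds
        rng = np.random.default_rng(8)
        x = rng.uniform(-1, 1, size=(30, 2))
        y = np.sin(2 * x[:, 0]) + x[:, 1]
        net_a, _ = lm_train(x, y, MLPConfig(max_iter=50), init_seed=2)
        net_b, _ = lm_train(x, 5.0 * y - 3.0, MLPConfig(max_iter=50),
                            init_seed=2)
        pred_a = net_a.forward(x)
        pred_b = (net_b.forward(x) + 3.0) / 5.0
        assert np.allclose(pred_a, pred_b, rtol=1e-8, atol=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="2"):
            lm_train(np.zeros((1, 2)), np.zeros(1))


class TestLMStepDirections:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.J = rng.normal(size=(30, 8))
        self.e = rng.normal(size=30)

    @staticmethod
    def _cos(a, b):
        return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

    def test_large_mu_approaches_gradient_direction(self):
        step = lm_step(self.J, self.e, mu=1e12)
        grad = self.J.T @ self.e
        assert self._cos(step, grad) > 1.0 - 1e-9

    def test_small_mu_approaches_gauss_newton(self):
        step = lm_step(self.J, self.e, mu=1e-12)
        gn = np.linalg.solve(self.J.T @ self.J, self.J.T @ self.e)
        assert self._cos(step, gn) > 1.0 - 1e-9
        assert np.allclose(step, gn, rtol=1e-6)


class TestTrainWithRestarts:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, size=(40, 2))
        y = x[:, 0] + x[:, 1] ** 2
        cfg = MLPConfig(max_iter=30, n_restarts=3, seed=7)
        net_a, rep_a = train_with_restarts(x[:30], y[:30], x[30:], y[30:], cfg)
        net_b, rep_b = train_with_restarts(x[:30], y[:30], x[30:], y[30:], cfg)
        assert rep_a == rep_b
        assert np.array_equal(net_a.W1, net_b.W1)
        assert net_a.seed == net_b.seed

    def test_identity_target(self):
        rng = np.random.default_rng(0)
        x = rng.permutation(np.linspace(-1, 1, 60))[:, None]
        y = x.ravel()
        cfg = MLPConfig(max_iter=200, n_restarts=5, seed=0)
        _, rep = train_with_restarts(x[:45], y[:45], x[45:], y[45:], cfg)
        assert rep.slope == pytest.approx(1.0, abs=1e-3)
        assert rep.intercept == pytest.approx(0.0, abs=1e-3)
        assert rep.r2 > 0.9999

    def test_restart_seeds_are_consecutive(self):
        x = np.linspace(-1, 1, 30)[:, None]
        y = np.sin(np.pi * x.ravel())
        cfg = MLPConfig(max_iter=20, n_restarts=4, seed=100)
        net, _ = train_with_restarts(x[:24], y[:24], x[24:], y[24:], cfg)
        assert net.seed in {100, 101, 102, 103}


class TestEvaluateFit:
    def test_identity(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = evaluate_fit(y, y)
        assert (rep.slope, rep.intercept, rep.r2) == (1.0, 0.0, 1.0)

    def test_collinear_scaling(self):
        y = np.array([1.0, 2.0, 5.0, 9.0])
        rep = evaluate_fit(y, 2.0 * y)
        assert rep.slope == pytest.approx(2.0)
        assert rep.intercept == pytest.approx(0.0)
        assert rep.r2 == pytest.approx(1.0)

    def test_noise_variance_oracle(self):
        rng = np.random.default_rng(0)
        n = 20000
        y = rng.normal(0.0, 2.0, n)
        eps = rng.normal(0.0, 0.5, n)
        rep = evaluate_fit(y, y + eps)
        expected = 1.0 - 0.25 / 4.0  # 1 - var(eps)/var(y)
        assert rep.r2 == pytest.approx(expected, abs=0.01)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            evaluate_fit(np.ones(5), np.arange(5.0))

    def test_length_contract(self):
        with pytest.raises(ValueError):
            evaluate_fit(np.ones(2), np.ones(2))


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        x = rng.uniform(-1, 1, size=(30, 3))
        y = x @ np.array([1.0, -2.0, 0.5])
        net, _ = lm_train(x, y, MLPConfig(max_iter=50), init_seed=1,
                          feature_names=["a", "b", "c"], target_name="t")
        path = tmp_path / "net.json"
        net.save(path)
        loaded = NeuralNet.load(path)
        assert loaded.target_name == "t"
        assert loaded.feature_names == ["a", "b", "c"]
        assert np.allclose(loaded.forward(x), net.forward(x))

    def test_unknown_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"schema": "other"}))
        with pytest.raises(ValueError, match="schema"):
            NeuralNet.load(path)
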