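"""Single-hidden-layer perceptron trained with Levenberg-Marquardt.

Architecture: standardized inputs -> sigmoid hidden layer -> linear output
-> destandardized prediction.  Training minimizes mean squared error on the
standardized scale with the damped Gauss-Newton (Levenberg-Marquardt)
update

    dw = (J^T J + mu I)^(-1) J^T e,

where J is the analytic Jacobian of the residuals with respect to every
weight and bias.  Steps are accepted only when the training MSE decreases
(mu is then relaxed); otherwise mu is inflated and the step retried, so
the accepted-step MSE sequence is non-increasing by construction.
Generalization control is multi-restart selection on an independent test
set rather than early stopping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MLPConfig",
    "NeuralNet",
    "FitReport",
    "TrainingTrace",
    "TrainingError",
    "lm_train",
    "lm_step",
    "train_with_restarts",
    "evaluate_fit",
]

_EPS_SCALE = 1e-12


class TrainingError(RuntimeError):
    """Raised when training cannot proceed (singular system, all restarts
    failed); carries the trace when available."""

    def __init__(self, message: str, trace: "TrainingTrace | None" = None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class MLPConfig:
    """Hyper-parameters of the net and its Levenberg-Marquardt trainer."""

    n_hidden: int = 10
    n_restarts: int = 10
    mu0: float = 1e-3
    mu_up: float = 10.0
    mu_down: float = 0.1
    max_iter: int = 200
    grad_tol: float = 1e-7
    mu_max: float = 1e10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if not (self.mu_up > 1.0 > self.mu_down > 0.0):
            raise ValueError("require mu_up > 1 > mu_down > 0")
        if self.max_iter < 1 or self.grad_tol < 0 or self.mu_max <= self.mu0:
            raise ValueError("invalid max_iter/grad_tol/mu_max")


@dataclass
class TrainingTrace:
    """Per-iteration record of one training run."""

    mse_path: list = field(default_factory=list)   # accepted-step MSE
    mu_path: list = field(default_factory=list)
    n_iterations: int = 0
    n_rejected: int = 0
    stop_reason: str = ""
    seed: int = 0


@dataclass
class NeuralNet:
    """Trained net: scalings plus hidden/output weights.

    ``W1`` is (n_hidden, n_inputs), ``b1`` is (n_hidden,), ``w2`` is
    (n_hidden,), ``b2`` scalar.  Hidden activation is the logistic
    sigmoid; the output is linear.
    """

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    feature_names: list = field(default_factory=list)
    target_name: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.x_mean = np.asarray(self.x_mean, dtype=float)
        self.x_scale = np.asarray(self.x_scale, dtype=float)
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        h, d = self.W1.shape
        if self.b1.shape != (h,) or self.w2.shape != (h,):
            raise ValueError("inconsistent hidden-layer dimensions")
        if self.x_mean.shape != (d,) or self.x_scale.shape != (d,):
            raise ValueError("input scaling dimension mismatch")
        if (not np.all(np.isfinite(self.x_scale)) or np.any(self.x_scale == 0)
                or self.y_scale == 0 or not np.isfinite(self.y_scale)):
            raise ValueError("scaling factors must be finite and nonzero")

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    def forward(self, x) -> np.ndarray | float:
        """Predict for one feature vector or a (n, d) batch."""
        arr = np.asarray(x, dtype=float)
        single = arr.ndim == 1
        X = np.atleast_2d(arr)
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"feature-count mismatch: net expects {self.n_inputs}, "
                f"got {X.shape[1]}")
        xs = (X - self.x_mean) / self.x_scale
        a = _sigmoid(xs @ self.W1.T + self.b1)
        ys = a @ self.w2 + self.b2
        y = ys * self.y_scale + self.y_mean
        return float(y[0]) if single else y

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": "mucosim-net-v1",
            "activation": "sigmoid",
            "output_activation": "linear",
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "feature_names": list(self.feature_names),
            "target_name": self.target_name,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuralNet":
        if d.get("schema") != "mucosim-net-v1":
            raise ValueError(f"unsupported net schema {d.get('schema')!r}")
        return cls(
            x_mean=d["x_mean"], x_scale=d["x_scale"],
            y_mean=float(d["y_mean"]), y_scale=float(d["y_scale"]),
            W1=d["W1"], b1=d["b1"], w2=d["w2"], b2=float(d["b2"]),
            feature_names=list(d.get("feature_names", [])),
            target_name=d.get("target_name", ""),
            seed=d.get("seed"),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "NeuralNet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class FitReport:
    """Least-squares line through (true, predicted) pairs plus test MSE."""

    slope: float
    intercept: float
    r2: float
    mse: float
    n: int


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _standardize(v: np.ndarray):
    mean = v.mean(axis=0)
    scale = v.std(axis=0)
    scale = np.where(np.abs(scale) < _EPS_SCALE, 1.0, scale)
    return mean, scale


def _unpack(w: np.ndarray, h: int, d: int):
    W1 = w[: h * d].reshape(h, d)
    b1 = w[h * d: h * d + h]
    w2 = w[h * d + h: h * d + 2 * h]
    b2 = w[-1]
    return W1, b1, w2, b2


def _residuals_and_jacobian(w, Xs, ys, h):
    n, d = Xs.shape
    W1, b1, w2, b2 = _unpack(w, h, d)
    a = _sigmoid(Xs @ W1.T + b1)          # (n, h)
    e = a @ w2 + b2 - ys                  # residuals
    da = a * (1.0 - a)                    # (n, h)
    J = np.empty((n, w.size))
    # d e / d W1[j, k] = w2[j] * da[:, j] * Xs[:, k]
    J[:, : h * d] = (da * w2).repeat(d, axis=1) * np.tile(Xs, (1, h))
    J[:, h * d: h * d + h] = da * w2
    J[:, h * d + h: h * d + 2 * h] = a
    J[:, -1] = 1.0
    return e, J


def lm_step(J: np.ndarray, e: np.ndarray, mu: float) -> np.ndarray:
    """One damped Gauss-Newton update dw = (J^T J + mu I)^(-1) J^T e."""
    A = J.T @ J + mu * np.eye(J.shape[1])
    return np.linalg.solve(A, J.T @ e)


def _init_weights(rng: np.random.Generator, h: int, d: int) -> np.ndarray:
    w = np.empty(h * d + 2 * h + 1)
    w[: h * d] = rng.uniform(-1, 1, h * d) / np.sqrt(d)
    w[h * d: h * d + h] = rng.uniform(-1, 1, h)
    w[h * d + h: h * d + 2 * h] = rng.uniform(-1, 1, h) / np.sqrt(h)
    w[-1] = 0.0
    return w


def lm_train(X, y, config: MLPConfig | None = None,
             init_seed: int | None = None,
             feature_names=None, target_name: str = "") -> tuple[NeuralNet, TrainingTrace]:
    """Train one net by Levenberg-Marquardt; returns (net, trace)."""
    config = config if config is not None else MLPConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if n != y.size:
        raise ValueError("X and y length mismatch")
    if n < 2:
        raise ValueError("need at least 2 training samples")
    seed = config.seed if init_seed is None else init_seed
    h = config.n_hidden

    x_mean, x_scale = _standardize(X)
    trace = TrainingTrace(seed=seed)

    if np.std(y) < _EPS_SCALE * max(1.0, np.abs(y).max()):
        # constant-target shortcut: a zero-weight net predicts the mean
        trace.stop_reason = "constant_target"
        net = NeuralNet(x_mean=x_mean, x_scale=x_scale,
                        y_mean=float(y.mean()), y_scale=1.0,
                        W1=np.zeros((h, d)), b1=np.zeros(h),
                        w2=np.zeros(h), b2=0.0,
                        feature_names=list(feature_names or []),
                        target_name=target_name, seed=seed)
        trace.mse_path.append(0.0)
        return net, trace

    y_mean, y_scale = float(y.mean()), float(y.std())
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale

    rng = np.random.default_rng(seed)
    w = _init_weights(rng, h, d)
    mu = config.mu0

    e, J = _residuals_and_jacobian(w, Xs, ys, h)
    mse = float(np.mean(e ** 2))
    trace.mse_path.append(mse)
    trace.mu_path.append(mu)

    for _ in range(config.max_iter):
        trace.n_iterations += 1
        grad = J.T @ e / e.size
        if np.max(np.abs(grad)) < config.grad_tol:
            trace.stop_reason = "grad_tol"
            break
        accepted = False
        while mu <= config.mu_max:
            try:
                dw = lm_step(J, e, mu)
            except np.linalg.LinAlgError as exc:
                raise TrainingError(
                    f"singular normal equations at mu = {mu:g}", trace
                ) from exc
            if not np.all(np.isfinite(dw)):
                mu *= config.mu_up
                continue
            w_new = w - dw
            e_new, J_new = _residuals_and_jacobian(w_new, Xs, ys, h)
            mse_new = float(np.mean(e_new ** 2))
            if np.isfinite(mse_new) and mse_new < mse:
                w, e, J, mse = w_new, e_new, J_new, mse_new
                mu = max(mu * config.mu_down, 1e-300)
                accepted = True
                trace.mse_path.append(mse)
                trace.mu_path.append(mu)
                break
            mu *= config.mu_up
            trace.n_rejected += 1
        if not accepted:
            trace.stop_reason = "mu_max"
            break
    else:
        trace.stop_reason = "max_iter"

    W1, b1, w2, b2 = _unpack(w, h, d)
    net = NeuralNet(x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
                    y_scale=y_scale, W1=W1, b1=b1, w2=w2, b2=float(b2),
                    feature_names=list(feature_names or []),
                    target_name=target_name, seed=seed)
    return net, trace


def train_with_restarts(X_train, y_train, X_test, y_test,
                        config: MLPConfig | None = None,
                        feature_names=None,
                        target_name: str = "") -> tuple[NeuralNet, FitReport]:
    """Train ``n_restarts`` nets from seeds seed, seed+1, ... and keep the
    one with the lowest test-set MSE (ties: lowest restart index)."""
    config = config if config is not None else MLPConfig()
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_test = np.asarray(y_test, dtype=float).ravel()
    best = None
    errors = []
    for k in range(config.n_restarts):
        try:
            net, trace = lm_train(X_train, y_train, config,
                                  init_seed=config.seed + k,
                                  feature_names=feature_names,
                                  target_name=target_name)
        except TrainingError as exc:
            errors.append(f"restart {k}: {exc}")
            continue
        pred = net.forward(X_test)
        test_mse = float(np.mean((pred - y_test) ** 2))
        if best is None or test_mse < best[0]:
            best = (test_mse, k, net)
    if best is None:
        raise TrainingError(
            f"all {config.n_restarts} restarts failed: {'; '.join(errors)}")
    test_mse, _, net = best
    report = evaluate_fit(y_test, net.forward(X_test))
    return net, report


def evaluate_fit(y_true, y_pred) -> FitReport:
    """Ordinary least squares of predictions on true values.

    slope/intercept define the line f(x) = slope * x + intercept fitted to
    (true, predicted) pairs; R^2 = 1 - SS_res / SS_tot of that regression.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 3:
        raise ValueError("need >= 3 equal-length samples")
    sxx = float(np.sum((y_true - y_true.mean()) ** 2))
    if sxx < _EPS_SCALE * max(1.0, float(np.abs(y_true).max()) ** 2):
        raise ValueError("R^2 undefined: y_true has zero variance")
    sxy = float(np.sum((y_true - y_true.mean()) * (y_pred - y_pred.mean())))
    slope = sxy / sxx
    intercept = float(y_pred.mean() - slope * y_true.mean())
    resid = y_pred - (slope * y_true + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y_pred - y_pred.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    mse = float(np.mean((y_pred - y_true) ** 2))
    return FitReport(slope=slope, intercept=intercept, r2=r2, mse=mse,
                     n=y_true.size)
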