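"""Feedforward networks mapping RDH features to normalized parameters.

Small fully connected ReLU networks trained with Adam on the mean-squared
loss.  An architecture is written as a tuple of hidden widths: ``(16, 16)``
is two hidden layers of 16 units, ``()`` a purely affine map.  Training
keeps the weight snapshot with the lowest validation loss seen along the
trajectory and stops early when the validation loss has not improved for a
given number of steps.

Implemented directly on numpy arrays: the networks here are tiny (a dozen
input features, at most a few hidden layers), so explicit forward/backward
passes are simple and fully deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["FFNNRegressor", "ffnn_forward", "train_ffnn", "TrainConfig",
           "init_weights", "schedule_for"]


@dataclass(frozen=True)
class TrainConfig:
    """Step budget ``max_steps``, early-stop patience, and optimizer knobs."""

    max_steps: int = 200_000
    patience: int = 50_000
    batch_size: int = 32
    learning_rate: float = 1e-3
    eval_interval: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience >= self.max_steps:
            raise ValueError("patience must be smaller than max_steps")


def schedule_for(n_points: int) -> tuple[int, int]:
    """(max_steps, patience) by dataset size: (4e5, 1e5) for up to ~50
    points, (2e5, 5e4) for mid-sized sets, (1e5, 2e4) from 5000 points on."""
    if n_points <= 50:
        return 400_000, 100_000
    if n_points < 5000:
        return 200_000, 50_000
    return 100_000, 20_000


def init_weights(hidden_sizes, input_dim: int, output_dim: int, rng) -> list:
    """He-scaled Gaussian weights and zero biases, layer by layer."""
    dims = [input_dim, *hidden_sizes, output_dim]
    weights = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in))
        b = np.zeros(d_out)
        weights.append((W, b))
    return weights


def ffnn_forward(weights: list, x: np.ndarray) -> np.ndarray:
    """Forward pass: ReLU hidden layers, affine output.

    ``x`` is one sample (1-D) or a batch with samples in rows.
    """
    a = np.atleast_2d(np.asarray(x, dtype=float))
    for W, b in weights[:-1]:
        a = np.maximum(0.0, a @ W.T + b)
    W, b = weights[-1]
    out = a @ W.T + b
    return out[0] if np.asarray(x).ndim == 1 else out


def _forward_cache(weights, X):
    acts = [X]
    for W, b in weights[:-1]:
        acts.append(np.maximum(0.0, acts[-1] @ W.T + b))
    W, b = weights[-1]
    return acts, acts[-1] @ W.T + b


def _backward(weights, acts, out, Y):
    """Gradients of the batch MSE with respect to every weight and bias."""
    batch = Y.shape[0]
    delta = 2.0 * (out - Y) / (batch * Y.shape[1])
    grads = [None] * len(weights)
    for layer in range(len(weights) - 1, -1, -1):
        W, _ = weights[layer]
        grads[layer] = (delta.T @ acts[layer], delta.sum(axis=0))
        if layer > 0:
            delta = (delta @ W) * (acts[layer] > 0)
    return grads


def train_ffnn(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray,
    Y_val: np.ndarray,
    hidden_sizes=(),
    config: TrainConfig | None = None,
) -> tuple[list, float]:
    """Adam training; returns the best-validation weight snapshot and loss."""
    config = config or TrainConfig()
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float))
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    Y_val = np.atleast_2d(np.asarray(Y_val, dtype=float))
    if Y_train.shape[0] == 1 and X_train.shape[0] > 1:
        Y_train = Y_train.T
    if Y_val.shape[0] == 1 and X_val.shape[0] > 1:
        Y_val = Y_val.T
    rng = np.random.default_rng(config.seed)
    weights = init_weights(hidden_sizes, X_train.shape[1], Y_train.shape[1], rng)

    mom = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    vel = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    n = X_train.shape[0]

    def val_loss(w):
        _, out = _forward_cache(w, X_val)
        return float(np.mean((out - Y_val) ** 2))

    best_loss = val_loss(weights)
    best_weights = [(W.copy(), b.copy()) for W, b in weights]
    best_step = 0
    for step in range(1, config.max_steps + 1):
        batch = rng.integers(0, n, size=min(config.batch_size, n))
        acts, out = _forward_cache(weights, X_train[batch])
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("training diverged (non-finite loss)")
        grads = _backward(weights, acts, out, Y_train[batch])
        new_weights = []
        for layer, ((W, b), (gW, gb)) in enumerate(zip(weights, grads)):
            mW, mb = mom[layer]
            vW, vb = vel[layer]
            mW = beta1 * mW + (1 - beta1) * gW
            mb = beta1 * mb + (1 - beta1) * gb
            vW = beta2 * vW + (1 - beta2) * gW**2
            vb = beta2 * vb + (1 - beta2) * gb**2
            mom[layer], vel[layer] = (mW, mb), (vW, vb)
            c1 = 1 - beta1**step
            c2 = 1 - beta2**step
            W = W - lr * (mW / c1) / (np.sqrt(vW / c2) + eps)
            b = b - lr * (mb / c1) / (np.sqrt(vb / c2) + eps)
            new_weights.append((W, b))
        weights = new_weights
        if step % config.eval_interval == 0 or step == config.max_steps:
            loss = val_loss(weights)
            if loss < best_loss:
                best_loss = loss
                best_weights = [(W.copy(), b.copy()) for W, b in weights]
                best_step = step
            elif step - best_step >= config.patience:
                break
    return best_weights, best_loss


class FFNNRegressor(RegressorMixin, BaseEstimator):
    """Feedforward ReLU network regressor (sklearn-style estimator).

    Inputs are standardized per feature with training-split statistics.
    ``fit`` accepts an explicit validation split (``X_val``, ``y_val``);
    without one a random 25% of the training data is held out.
    """

    def __init__(
        self,
        hidden_sizes=(),
        max_steps: int = 20_000,
        patience: int = 5_000,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.max_steps = max_steps
        self.patience = patience
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        y2 = y.reshape(-1, 1) if y.ndim == 1 else y
        if X_val is None:
            rng = np.random.default_rng(self.seed)
            perm = rng.permutation(X.shape[0])
            n_val = max(1, X.shape[0] // 4)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X, X_val = X[tr_idx], X[val_idx]
            y2, y_val = y2[tr_idx], y2[val_idx]
        else:
            X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
            y_val = np.asarray(y_val, dtype=float)
            y_val = y_val.reshape(-1, 1) if y_val.ndim == 1 else y_val
        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xs = (X - self.x_mean_) / self.x_std_
        Xv = (X_val - self.x_mean_) / self.x_std_
        config = TrainConfig(
            max_steps=self.max_steps,
            patience=self.patience,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.seed,
        )
        self.weights_, self.best_val_loss_ = train_ffnn(
            Xs, y2, Xv, y_val, hidden_sizes=tuple(self.hidden_sizes), config=config
        )
        self._single_output = y.ndim == 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = ffnn_forward(self.weights_, (X - self.x_mean_) / self.x_std_)
        return out[:, 0] if self._single_output else out
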