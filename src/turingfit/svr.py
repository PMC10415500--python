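"""Epsilon-insensitive kernel support-vector regression without bias term.

The primal problem over coefficients ``alpha`` and slacks ``xi`` is

    min  sum_i xi_i + (lambda/2) alpha^T K alpha
    s.t. xi_i >= 0,
         xi_i + (K alpha)_i >= y_i - eps,
         xi_i - (K alpha)_i >= -y_i - eps,

i.e. the epsilon-insensitive loss on the kernel expansion
``f(x) = sum_i alpha_i k(x_i, x)`` plus an RKHS-norm penalty; there is no
offset term (normalized nonnegative targets keep predictions in range).

The solver works on the exact Lagrangian dual, a box-constrained problem in
``beta = lambda * alpha``:

    min  (1/(2 lambda)) beta^T K beta - y^T beta + eps * ||beta||_1,
    s.t. |beta_i| <= 1,

solved by cyclic coordinate descent with closed-form soft-threshold/clip
updates.  Strong duality holds (convex QP with strictly feasible points),
so the primal optimum is recovered as ``alpha = beta / lambda`` with slacks
``xi_i = max(0, |y_i - (K alpha)_i| - eps)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .kernels import KernelSpec, gram

__all__ = ["KernelSVR", "SVRModel", "train_svr", "predict_svr", "solve_svr_qp"]

_JITTER = 1e-10


def solve_svr_qp(
    K: np.ndarray,
    y: np.ndarray,
    lam: float,
    epsilon: float,
    tol: float = 1e-12,
    max_cycles: int = 20000,
) -> tuple[np.ndarray, float]:
    """Solve the SVR quadratic program; returns ``(alpha, objective)``.

    ``K`` must be symmetric PSD up to small jitter; ``lam > 0``,
    ``epsilon >= 0``.  The attained primal objective is reported.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if K.shape != (n, n):
        raise ValueError("Gram matrix / target size mismatch")
    if lam <= 0:
        raise ValueError("lam must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("Gram matrix must be symmetric")
    K = 0.5 * (K + K.T)
    diag = np.diag(K).copy() + _JITTER
    if np.any(diag <= 0):
        raise ValueError("Gram matrix diagonal must be nonnegative")

    beta = np.zeros(n)
    Kbeta = np.zeros(n)
    thresh = lam * epsilon
    scale = max(1.0, np.abs(y).max()) if n else 1.0
    for _ in range(max_cycles):
        max_delta = 0.0
        for i in range(n):
            g = lam * y[i] - (Kbeta[i] - K[i, i] * beta[i])
            cand = np.sign(g) * max(0.0, abs(g) - thresh) / diag[i]
            new = min(1.0, max(-1.0, cand))
            d = new - beta[i]
            if d != 0.0:
                Kbeta += d * K[:, i]
                beta[i] = new
                max_delta = max(max_delta, abs(d))
        if max_delta <= tol * scale:
            break
    alpha = beta / lam
    resid = np.abs(y - Kbeta / lam) - epsilon
    xi = np.clip(resid, 0.0, None)
    objective = float(xi.sum() + 0.5 * lam * alpha @ (K @ alpha))
    return alpha, objective


@dataclass
class SVRModel:
    """Trained SVR: kernel expansion coefficients plus training inputs."""

    alpha: np.ndarray
    train_inputs: np.ndarray
    kernel_spec: KernelSpec
    epsilon_tube: float
    lam: float
    objective_value: float = field(default=np.nan)


class KernelSVR(RegressorMixin, BaseEstimator):
    """Scalar-output SVR with a histogram kernel (sklearn-style estimator).

    Parameters
    ----------
    kernel : str
        Kernel family: "wasserstein", "exp_chi2", "chi2" or "gaussian".
    gamma : float
        Kernel scale (unused for "chi2").
    lam : float
        RKHS regularization weight (> 0).
    epsilon : float
        Half-width of the insensitive tube (on normalized targets).
    """

    def __init__(
        self,
        kernel: str = "wasserstein",
        gamma: float = 1.0,
        lam: float = 1e-3,
        epsilon: float = 0.01,
    ):
        self.kernel = kernel
        self.gamma = gamma
        self.lam = lam
        self.epsilon = epsilon

    def _spec(self) -> KernelSpec:
        gamma = None if self.kernel == "chi2" else self.gamma
        return KernelSpec(family=self.kernel, gamma=gamma)

    def fit(self, X, y, gram_matrix: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on the sample count")
        K = gram(X, self._spec()) if gram_matrix is None else np.asarray(gram_matrix)
        alpha, obj = solve_svr_qp(K, y, self.lam, self.epsilon)
        self.X_train_ = X
        self.alpha_ = alpha
        self.objective_value_ = obj
        self.gram_ = K
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "alpha_")
        X = np.asarray(X, dtype=float)
        Kx = gram(self.X_train_, self._spec(), X)  # (n_train, n_test)
        return self.alpha_ @ Kx

    def to_model(self) -> SVRModel:
        check_is_fitted(self, "alpha_")
        return SVRModel(
            alpha=self.alpha_,
            train_inputs=self.X_train_,
            kernel_spec=self._spec(),
            epsilon_tube=self.epsilon,
            lam=self.lam,
            objective_value=self.objective_value_,
        )


def train_svr(
    K_n: np.ndarray,
    y: np.ndarray,
    lam: float,
    epsilon_tube: float,
    train_inputs: np.ndarray | None = None,
    kernel_spec: KernelSpec | None = None,
) -> SVRModel:
    """Train from a precomputed Gram matrix (thin functional wrapper)."""
    alpha, obj = solve_svr_qp(K_n, y, lam, epsilon_tube)
    return SVRModel(
        alpha=alpha,
        train_inputs=np.asarray(train_inputs) if train_inputs is not None else None,
        kernel_spec=kernel_spec or KernelSpec("wasserstein", 1.0),
        epsilon_tube=epsilon_tube,
        lam=lam,
        objective_value=obj,
    )


def predict_svr(model: SVRModel, x) -> float:
    """Evaluate ``f(x) = sum_i alpha_i k(x_i, x)`` at a single feature point."""
    if model.train_inputs is None:
        raise ValueError("model lacks stored training inputs")
    kx = gram(model.train_inputs, model.kernel_spec, [np.asarray(x, dtype=float)])
    return float(model.alpha @ kx[:, 0])
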