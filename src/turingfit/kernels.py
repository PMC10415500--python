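"""Histogram kernels for RDHs and the Gaussian output kernel.

Histograms live in the probability simplex.  The symmetric chi-squared
kernel ``sum_i x_i x'_i / (x_i + x'_i)`` and its exponential variant are
generated by Hilbertian metrics on probability measures.  The Wasserstein
kernel ``exp(-d_W^2 / gamma)`` uses the squared order-2 optimal-transport
distance with ground cost ``C_ij = (i - j)^2`` on bin indices; for 1-D
histograms the transport optimum has the closed form of an integral of the
squared difference of generalized inverse CDFs, evaluated exactly on the
merged cumulative breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelSpec", "chi2_kernel", "exp_chi2_kernel", "wasserstein_sq",
    "wasserstein_kernel", "gaussian_kernel", "gram", "kernel_function",
]

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus scale. ``gamma`` is ignored for plain chi2."""

    family: str  # chi2 | exp_chi2 | wasserstein | gaussian
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("chi2", "exp_chi2", "wasserstein", "gaussian"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family != "chi2" and (self.gamma is None or self.gamma <= 0):
            raise ValueError(f"{self.family} kernel needs gamma > 0")


def chi2_kernel(x, y) -> float:
    """Symmetric chi-squared kernel; 0/0 summands contribute 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(s > 0, x * y / np.where(s > 0, s, 1.0), 0.0)
    return float(terms.sum())


def exp_chi2_kernel(x, y, gamma: float) -> float:
    """Exponential chi-squared kernel ``exp(-chi2_dist / gamma)``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(s > 0, (x - y) ** 2 / np.where(s > 0, s, 1.0), 0.0)
    return float(np.exp(-terms.sum() / gamma))


def _check_simplex(x: np.ndarray) -> np.ndarray:
    if np.any(x < -_MASS_TOL):
        raise ValueError("histogram has negative mass")
    total = x.sum()
    if abs(total - 1.0) > _MASS_TOL:
        raise ValueError(f"histogram mass {total} differs from 1 beyond tolerance")
    x = np.clip(x, 0.0, None)
    return x / x.sum()


def wasserstein_sq(x, y) -> float:
    """Squared order-2 Wasserstein distance between two B-bin histograms.

    Ground cost is the squared bin-index difference, so distances are in
    units of bins squared.  Computed by integrating the squared difference
    of the generalized inverse CDFs over the merged cumulative breakpoints;
    this equals the optimum of the transport linear program.
    """
    x = _check_simplex(np.asarray(x, dtype=float))
    y = _check_simplex(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("histograms must have the same bin count")
    cx = np.cumsum(x)
    cy = np.cumsum(y)
    levels = np.union1d(cx, cy)
    levels = levels[levels <= 1.0 + _MASS_TOL]
    # mass in segment s is levels[s] - levels[s-1]; the quantile index of a
    # level interval (lo, hi] is the first bin whose CDF reaches hi
    seg_mass = np.diff(np.concatenate([[0.0], levels]))
    qx = np.searchsorted(cx, levels - 1e-15)
    qy = np.searchsorted(cy, levels - 1e-15)
    qx = np.minimum(qx, x.size - 1)
    qy = np.minimum(qy, y.size - 1)
    keep = seg_mass > 1e-15  # skip zero-mass segments (ties in the CDFs)
    return float(np.sum(seg_mass[keep] * (qx[keep] - qy[keep]) ** 2))


def wasserstein_kernel(x, y, gamma: float) -> float:
    """Wasserstein kernel ``exp(-d_W^2(x, y) / gamma)``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(np.exp(-wasserstein_sq(x, y) / gamma))


def gaussian_kernel(x, y, gamma: float) -> float:
    """Gaussian kernel ``exp(-||x - y||^2 / gamma)`` on vectors."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return float(np.exp(-np.dot(d, d) / gamma))


def kernel_function(spec: KernelSpec):
    """Binary kernel callable for a :class:`KernelSpec`."""
    if spec.family == "chi2":
        return chi2_kernel
    if spec.family == "exp_chi2":
        return lambda x, y: exp_chi2_kernel(x, y, spec.gamma)
    if spec.family == "wasserstein":
        return lambda x, y: wasserstein_kernel(x, y, spec.gamma)
    return lambda x, y: gaussian_kernel(x, y, spec.gamma)


def gram(X, spec: KernelSpec, Y=None) -> np.ndarray:
    """Gram matrix ``K[i, j] = k(X[i], Y[j])`` (``Y = X`` when omitted).

    The square case exploits symmetry and fills both triangles.
    """
    X = [np.asarray(x, dtype=float) for x in X]
    if len(X) == 0:
        raise ValueError("empty input")
    k = kernel_function(spec)
    if Y is None:
        n = len(X)
        K = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                K[i, j] = K[j, i] = k(X[i], X[j])
        return K
    Y = [np.asarray(y, dtype=float) for y in Y]
    K = np.empty((len(X), len(Y)))
    for i, xi in enumerate(X):
        for j, yj in enumerate(Y):
            K[i, j] = k(xi, yj)
    return K
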