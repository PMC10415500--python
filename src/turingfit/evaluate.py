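"""Metrics, target normalization, data splitting/averaging and grid search.

The evaluation protocol: each dataset is split into disjoint train /
validation / test parts (60/20/20); hyperparameters minimize the validation
NRMSE on a grid; the test NRMSE is reported once.  For small dataset sizes
``m`` the NRMSE is averaged over the ``floor(P/m)`` disjoint subsets of a
larger pool, each independently split and trained, to damp the variance of
single small splits.

NRMSE = RMSE divided by the mean of the (nonnegative) target values over
the same evaluation points, so 0.2 means errors of about 20% of the typical
parameter magnitude.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TargetScaler", "normalize_targets", "nrmse", "split_dataset",
    "averaged_nrmse", "grid_search", "mean_predictor_nrmse",
]


class TargetScaler:
    """Per-column max normalization ``y' = y / max_column(y)`` with inverse."""

    def fit(self, Y: np.ndarray) -> "TargetScaler":
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        maxima = Y.max(axis=0)
        if np.any(maxima <= 0):
            raise ValueError("every target column needs a positive maximum")
        self.maxima_ = maxima
        return self

    def transform(self, Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        return Y / self.maxima_

    def fit_transform(self, Y: np.ndarray) -> np.ndarray:
        return self.fit(Y).transform(Y)

    def inverse_transform(self, Yn: np.ndarray) -> np.ndarray:
        return np.asarray(Yn, dtype=float) * self.maxima_


def normalize_targets(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized targets and the stored per-column maxima."""
    scaler = TargetScaler().fit(np.atleast_2d(np.asarray(Y, dtype=float)))
    Y2 = np.atleast_2d(np.asarray(Y, dtype=float))
    return scaler.transform(Y2), scaler.maxima_


def nrmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Root-mean-square error over all entries, divided by the mean truth."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.ndim == 1:
        pred = pred.reshape(-1, 1)
    if truth.ndim == 1:
        truth = truth.reshape(-1, 1)
    if pred.shape != truth.shape:
        raise ValueError("prediction / truth shape mismatch")
    mean = truth.mean()
    if mean <= 0:
        raise ValueError("NRMSE needs targets with positive mean")
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    return rmse / float(mean)


def split_dataset(n: int, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint 60/20/20 train/validation/test index partition."""
    if n < 5:
        raise ValueError("need at least 5 points to split 60/20/20")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(round(0.2 * n))
    n_test = int(round(0.2 * n))
    val = perm[:n_val]
    test = perm[n_val : n_val + n_test]
    train = perm[n_val + n_test :]
    return np.sort(train), np.sort(val), np.sort(test)


def _as_2d(Y):
    Y = np.asarray(Y, dtype=float)
    return Y.reshape(-1, 1) if Y.ndim == 1 else Y


def averaged_nrmse(
    features: np.ndarray,
    targets: np.ndarray,
    m: int,
    train_fn,
    seed: int = 0,
    average_threshold: int = 500,
) -> float:
    """Mean test NRMSE over disjoint subsets of size ``m`` of the pool.

    ``train_fn(X_train, Y_train, X_val, Y_val)`` must return a predictor
    callable.  For ``m`` above ``average_threshold`` a single subset is
    used.  Each subset is normalized, split 60/20/20, trained and tested
    independently.
    """
    X = np.asarray(features, dtype=float)
    Y = _as_2d(targets)
    P = X.shape[0]
    if m > P or P // m == 0:
        raise ValueError("subset size exceeds the pool")
    n_subsets = P // m if m <= average_threshold else 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(P)
    scores = []
    for s in range(n_subsets):
        idx = perm[s * m : (s + 1) * m]
        Xs, Ys = X[idx], Y[idx]
        Yn, _ = normalize_targets(Ys)
        tr, va, te = split_dataset(m, seed=seed + 1000 + s)
        predictor = train_fn(Xs[tr], Yn[tr], Xs[va], Yn[va])
        scores.append(nrmse(predictor(Xs[te]), Yn[te]))
    return float(np.mean(scores))


def mean_predictor_nrmse(truth: np.ndarray, train_mean: float | np.ndarray) -> float:
    """NRMSE of the trivial predictor that always outputs the training mean."""
    truth = _as_2d(truth)
    pred = np.broadcast_to(np.atleast_1d(train_mean), truth.shape)
    return nrmse(pred, truth)


@dataclass
class GridSearchResult:
    best_params: dict
    best_val_nrmse: float
    test_nrmse: float | None


def grid_search(
    train_fn,
    grids: dict,
    X_train, Y_train, X_val, Y_val,
    X_test=None, Y_test=None,
    refine: int = 0,
    refine_factor: float = 3.0,
) -> GridSearchResult:
    """Pick the hyperparameter combination minimizing validation NRMSE.

    ``train_fn(params, X_train, Y_train) -> predictor``.  Grid points are
    visited in lexicographic order and ties keep the first minimizer, so
    the search is deterministic.  ``refine > 0`` reruns the search on a
    geometric grid ``refine_factor`` times finer centered on the optimum.
    The test NRMSE is evaluated once, for the final winner.
    """
    keys = sorted(grids)
    if any(len(grids[k]) == 0 for k in keys):
        raise ValueError("empty hyperparameter grid")
    Y_val2 = _as_2d(Y_val)
    best = None
    for combo in itertools.product(*(grids[k] for k in keys)):
        params = dict(zip(keys, combo))
        try:
            predictor = train_fn(params, X_train, Y_train)
            score = nrmse(predictor(X_val), Y_val2)
        except (ValueError, RuntimeError, FloatingPointError):
            continue
        if best is None or score < best[0]:
            best = (score, params, predictor)
    if best is None:
        raise RuntimeError("every grid point failed to train")
    score, params, predictor = best
    for _ in range(refine):
        finer = {}
        for k in keys:
            center = params[k]
            if isinstance(center, (int, float)) and not isinstance(center, bool):
                f = refine_factor ** 0.5
                finer[k] = [center / f, center, center * f]
            else:
                finer[k] = [center]
        sub = grid_search(train_fn, finer, X_train, Y_train, X_val, Y_val)
        if sub.best_val_nrmse < score:
            score, params = sub.best_val_nrmse, sub.best_params
            predictor = train_fn(params, X_train, Y_train)
    test_score = None
    if X_test is not None and Y_test is not None:
        test_score = nrmse(predictor(X_test), _as_2d(Y_test))
    return GridSearchResult(best_params=params, best_val_nrmse=score, test_nrmse=test_score)
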