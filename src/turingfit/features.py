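"""Invariant pattern features: weighted pattern graphs, effective resistances,
resistance-distance histograms (RDHs) and two scalar descriptors.

A steady-state pattern is turned into a weighted torus graph: edges whose two
endpoints lie on the same side of the mean concentration get unit weight,
edges crossing the mean get a small weight ``eps_w`` (high conductance within
plateaus, low conductance across interfaces).  The effective resistance
between nodes of this graph measures nonlocal pattern structure; collecting
resistances between every source node and all nodes within a spatial radius
``r`` and binning them yields the RDH, a point in the probability simplex
that is invariant to cyclic shifts, rotations by 90 degrees and reflections
of the pattern.

Effective resistances derive from the graph Laplacian ``L_G``:
``R(v, v') = K_vv + K_v'v' - 2 K_vv'`` with ``K = (J + L_G)^(-1)`` (``J`` the
all-ones matrix); the ``J`` contributions cancel in the difference, so ``K``
may be replaced by the Moore-Penrose pseudoinverse of ``L_G`` or by a
grounded-node inverse, which is what the fast path uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _csgraph_components
from scipy.sparse.linalg import splu

__all__ = [
    "PatternGraph", "ResistanceData", "RDHFeature", "pattern_graph",
    "resistance_matrix", "collect_resistance_values", "rdh", "rdh_from_values",
    "pattern_rdh", "calibrate_rmax", "max_concentration",
    "connected_components_feature", "torus_offsets",
]

DEFAULT_EPS_W = 0.003
DEFAULT_BINS = 12


@dataclass
class PatternGraph:
    """Weighted 4-neighbor torus graph of a pattern.

    ``w_right[i, j]`` weights the edge from node ``(i, j)`` to ``(i, j+1)``
    (column wrap), ``w_down[i, j]`` the edge to ``(i+1, j)`` (row wrap);
    together these enumerate each of the ``2 n_r^2`` torus edges once.
    """

    n_r: int
    w_right: np.ndarray
    w_down: np.ndarray
    eps_w: float = DEFAULT_EPS_W

    def laplacian(self) -> sp.csr_matrix:
        """Sparse weighted graph Laplacian ``D - Omega``."""
        n = self.n_r
        m = n * n
        idx = np.arange(m).reshape(n, n)
        right = np.roll(idx, -1, axis=1).ravel()
        down = np.roll(idx, -1, axis=0).ravel()
        rows = np.concatenate([idx.ravel(), idx.ravel()])
        cols = np.concatenate([right, down])
        w = np.concatenate([self.w_right.ravel(), self.w_down.ravel()])
        adj = sp.coo_matrix((w, (rows, cols)), shape=(m, m))
        adj = adj + adj.T
        deg = np.asarray(adj.sum(axis=1)).ravel()
        return (sp.diags(deg) - adj).tocsr()


@dataclass
class ResistanceData:
    """Symmetric node-node effective-resistance matrix (zero diagonal)."""

    R: np.ndarray


@dataclass
class RDHFeature:
    """Normalized B-bin resistance-distance histogram plus optional scalars."""

    hist: np.ndarray
    r: float
    t: int = 1
    B: int = DEFAULT_BINS
    r_max: float = np.nan
    extras: dict = field(default_factory=dict)

    def vector(self, with_extras: tuple = ()) -> np.ndarray:
        """Histogram optionally concatenated with named extras."""
        parts = [np.asarray(self.hist, dtype=float)]
        for name in with_extras:
            parts.append(np.atleast_1d(float(self.extras[name])))
        return np.concatenate(parts)


def pattern_graph(field: np.ndarray, eps_w: float = DEFAULT_EPS_W) -> PatternGraph:
    """Assign edge weights from a single-species concentration grid.

    An edge gets weight 1 when both endpoint values are on the same side of
    the grid mean (both >= mean or both < mean) and ``eps_w`` otherwise.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 2 or field.shape[0] != field.shape[1]:
        raise ValueError("field must be a square 2-D grid")
    if field.shape[0] < 4:
        raise ValueError("n_r >= 4 required")
    if not np.all(np.isfinite(field)):
        raise ValueError("field must be finite")
    high = field >= field.mean()
    same_right = high == np.roll(high, -1, axis=1)
    same_down = high == np.roll(high, -1, axis=0)
    w_right = np.where(same_right, 1.0, eps_w)
    w_down = np.where(same_down, 1.0, eps_w)
    return PatternGraph(n_r=field.shape[0], w_right=w_right, w_down=w_down, eps_w=eps_w)


def _as_laplacian(graph) -> sp.csr_matrix:
    """Laplacian from a PatternGraph or a weighted adjacency matrix."""
    if isinstance(graph, PatternGraph):
        return graph.laplacian()
    adj = sp.csr_matrix(graph, dtype=float)
    if (abs(adj - adj.T) > 1e-12).nnz:
        raise ValueError("adjacency must be symmetric")
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return (sp.diags(deg) - adj).tocsr()


def _check_connected(lap: sp.csr_matrix) -> None:
    ncomp, _ = _csgraph_components(abs(lap), directed=False)
    if ncomp > 1:
        raise ValueError("graph is disconnected; resistances are undefined")


def resistance_matrix(graph) -> ResistanceData:
    """Full effective-resistance matrix via ``K = (J + L_G)^(-1)``.

    Dense; intended for small graphs.  ``graph`` is a :class:`PatternGraph`
    or any symmetric weighted adjacency matrix of a connected graph.
    """
    lap = _as_laplacian(graph)
    _check_connected(lap)
    m = lap.shape[0]
    K = np.linalg.inv(np.ones((m, m)) + lap.toarray())
    d = np.diag(K)
    R = d[:, None] + d[None, :] - 2.0 * K
    np.fill_diagonal(R, 0.0)
    return ResistanceData(R=R)


def _grounded_inverse(lap: sp.csr_matrix) -> np.ndarray:
    """Dense inverse of the Laplacian with node 0 grounded, padded with a
    zero row/column for the grounded node.

    For any nodes ``v, v'``: ``R(v, v') = M_vv + M_v'v' - 2 M_vv'``.
    """
    m = lap.shape[0]
    reduced = lap[1:, :][:, 1:].tocsc()
    # symmetric minimum-degree ordering suits the (symmetric) Laplacian
    lu = splu(reduced, permc_spec="MMD_AT_PLUS_A")
    inv = lu.solve(np.eye(m - 1))
    M = np.zeros((m, m))
    M[1:, 1:] = 0.5 * (inv + inv.T)
    return M


def torus_offsets(n_r: int, r: float) -> np.ndarray:
    """All nonzero ``(di, dj)`` offsets with toroidal Euclidean distance <= r.

    Distances use the minimal image convention consistent with the periodic
    boundary conditions of the simulation domain.
    """
    d = np.arange(n_r)
    d = np.minimum(d, n_r - d)
    dist2 = d[:, None] ** 2 + d[None, :] ** 2
    mask = dist2 <= r * r
    mask[0, 0] = False
    di, dj = np.nonzero(mask)
    return np.stack([di, dj], axis=1)


def collect_resistance_values(
    field: np.ndarray,
    r: float,
    t: int = 1,
    eps_w: float = DEFAULT_EPS_W,
) -> np.ndarray:
    """Multiset of resistance values of one pattern (before binning).

    Collects ``R(v, v')`` for every source node ``v`` of the undersampled
    grid ``V_t`` (every ``t``-th row and column) and every node ``v'`` with
    toroidal distance ``0 < ||r_v - r_v'|| <= r``.
    """
    graph = pattern_graph(field, eps_w)
    n = graph.n_r
    m = n * n
    lap = graph.laplacian()
    _check_connected(lap)
    M = _grounded_inverse(lap)
    diag = np.ascontiguousarray(np.diag(M))
    idx = np.arange(m).reshape(n, n)
    src = idx[::t, ::t].ravel()
    offsets = torus_offsets(n, r)
    out = np.empty(src.size * offsets.shape[0])
    pos = 0
    src_rows, src_cols = src // n, src % n
    for di, dj in offsets:
        tgt = ((src_rows + di) % n) * n + (src_cols + dj) % n
        out[pos : pos + src.size] = diag[src] + diag[tgt] - 2.0 * M[src, tgt]
        pos += src.size
    return out


def rdh_from_values(
    values: np.ndarray, B: int, r_max: float, r: float = np.nan, t: int = 1
) -> RDHFeature:
    """Bin collected resistance values into a normalized B-bin histogram.

    Uniform bins on ``[0, r_max]``, half-open with the last bin closed at
    ``r_max`` (numpy convention); values above ``r_max`` are dropped before
    normalization.  An all-dropped multiset signals a miscalibrated
    ``r_max``.
    """
    if B < 1 or r_max <= 0:
        raise ValueError("need B >= 1 and r_max > 0")
    values = np.asarray(values, dtype=float)
    kept = values[values <= r_max]
    if kept.size == 0:
        raise ValueError("all resistance values exceed r_max; recalibrate")
    counts, _ = np.histogram(kept, bins=B, range=(0.0, r_max))
    hist = counts / counts.sum()
    return RDHFeature(hist=hist, r=r, t=t, B=B, r_max=r_max)


def rdh(
    res: ResistanceData,
    n_r: int,
    r: float,
    t: int = 1,
    B: int = DEFAULT_BINS,
    r_max: float = 1.0,
) -> RDHFeature:
    """RDH from a precomputed full resistance matrix (small grids, tests)."""
    R = res.R
    m = R.shape[0]
    if m != n_r * n_r:
        raise ValueError("resistance matrix does not match the grid size")
    idx = np.arange(m).reshape(n_r, n_r)
    src = idx[::t, ::t].ravel()
    offsets = torus_offsets(n_r, r)
    src_rows, src_cols = src // n_r, src % n_r
    vals = []
    for di, dj in offsets:
        tgt = ((src_rows + di) % n_r) * n_r + (src_cols + dj) % n_r
        vals.append(R[src, tgt])
    values = np.concatenate(vals) if vals else np.empty(0)
    feat = rdh_from_values(values, B=B, r_max=r_max, r=r, t=t)
    return feat


def pattern_rdh(
    field: np.ndarray,
    r: float,
    r_max: float,
    t: int = 1,
    B: int = DEFAULT_BINS,
    eps_w: float = DEFAULT_EPS_W,
    extras: tuple = (),
) -> RDHFeature:
    """Full pipeline: pattern grid -> weighted graph -> resistances -> RDH."""
    values = collect_resistance_values(field, r=r, t=t, eps_w=eps_w)
    feat = rdh_from_values(values, B=B, r_max=r_max, r=r, t=t)
    if "cm" in extras:
        feat.extras["cm"] = max_concentration(field)
    if "nc" in extras:
        feat.extras["nc"] = connected_components_feature(field)
    return feat


def calibrate_rmax(resistance_value_sets) -> float:
    """Histogram upper edge: max over patterns of each pattern's 99% quantile.

    Discards the few very large resistance values that arise from numerical
    inaccuracies while keeping the bulk of every pattern's distribution.
    """
    sets = list(resistance_value_sets)
    if not sets:
        raise ValueError("need at least one pattern")
    return float(max(np.quantile(np.asarray(v, dtype=float), 0.99) for v in sets))


def max_concentration(field: np.ndarray, bins: int = 25, peak_floor: float = 0.01) -> float:
    """Location of the right-most peak of the concentration histogram.

    Values are binned into ``bins`` equal-width bins over ``[min, max]``.
    A peak is a bin whose count is a local maximum and holds at least
    ``peak_floor`` of all pixels (discarding isolated numerically inflated
    pixels); the center of the right-most such bin is returned.  A constant
    field returns its value.
    """
    field = np.asarray(field, dtype=float)
    lo, hi = float(field.min()), float(field.max())
    if hi == lo:
        return lo
    counts, edges = np.histogram(field.ravel(), bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    floor = peak_floor * field.size
    padded = np.concatenate([[-1.0], counts.astype(float), [-1.0]])
    is_peak = (padded[1:-1] >= padded[:-2]) & (padded[1:-1] >= padded[2:]) & (
        counts >= floor
    )
    if not np.any(is_peak):
        # fall back to the best-populated bin
        return float(centers[int(np.argmax(counts))])
    return float(centers[np.nonzero(is_peak)[0][-1]])


def connected_components_feature(field: np.ndarray) -> int:
    """Number of connected components of the high-concentration subgraph.

    Nodes with value >= grid mean are kept; edges of the torus grid between
    two kept nodes survive.  Counts the components of that subgraph (0 when
    no node reaches the mean, which can only occur through ties).
    """
    field = np.asarray(field, dtype=float)
    n = field.shape[0]
    high = field >= field.mean()
    k = int(high.sum())
    if k == 0:
        return 0
    label = -np.ones(field.shape, dtype=np.int64)
    label[high] = np.arange(k)
    rows = []
    cols = []
    for axis in (0, 1):
        nb = np.roll(label, -1, axis=axis)
        both = (label >= 0) & (nb >= 0)
        rows.append(label[both])
        cols.append(nb[both])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    adj = sp.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(k, k))
    ncomp, _ = _csgraph_components(adj, directed=False)
    return int(ncomp)
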