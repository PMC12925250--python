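"""Spatial neighbourhood weight matrices.

The spatial layout of an experiment enters the analysis only through a
sparse, symmetric, non-negative weight matrix ``W`` with zero diagonal:
``w_ij > 0`` encodes spatial proximity of spots *i* and *j*.  Three builders
are provided:

* :func:`build_grid_weights` — unit weights between lattice neighbours
  (the 8-neighbourhood on a rectangular grid, 6 on a hexagonal Visium
  layout), the default for gridded spatial transcriptomics arrays;
* :func:`build_knn_weights` — unit weights on the symmetrized k-nearest
  neighbour graph, for irregular spot positions;
* :func:`build_gaussian_weights` — Gaussian kernel weights over the k
  nearest neighbours with per-spot bandwidths calibrated to a fixed
  perplexity (effective neighbour count), then symmetrized.

Moran's I and Geary's C are invariant under a global rescaling of ``W``,
so only the *relative* weights matter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite
from scipy.spatial import cKDTree

__all__ = [
    "Coordinates",
    "WeightMatrix",
    "build_grid_weights",
    "build_knn_weights",
    "build_gaussian_weights",
]


@dataclass
class Coordinates:
    """Spot identifiers and planar positions, in grid or physical units.

    Row order is meaningful: it must match the spot order of the expression
    matrix the weights will be used with.  ``torus_extent``, when set to
    ``(width, height)``, declares that distances wrap around the lattice
    edges; this is a testing device that makes every spot an interior spot.
    """

    spot_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    torus_extent: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.spot_ids) == self.x.shape[0] == self.y.shape[0]):
            raise ValueError("spot_ids, x and y must have equal length")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("duplicate spot ids")
        if len(set(zip(self.x.tolist(), self.y.tolist()))) != self.n:
            raise ValueError("duplicate spot coordinates")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class WeightMatrix:
    """Sparse symmetric non-negative spot-adjacency matrix with zero diagonal."""

    W: sp.csr_matrix
    n_neighbors: int
    kernel: str
    total_weight: float = field(init=False)

    def __post_init__(self) -> None:
        W = sp.csr_matrix(self.W)
        W.eliminate_zeros()
        if (W != W.T).nnz:
            raise ValueError("weight matrix must be exactly symmetric")
        if W.diagonal().any():
            raise ValueError("weight matrix must have zero diagonal")
        if W.nnz and W.data.min() < 0:
            raise ValueError("weight matrix entries must be non-negative")
        self.W = W
        self.total_weight = float(W.sum())
        if self.total_weight <= 0:
            raise ValueError("empty weight matrix: all spots are isolated")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def to_mtx(self, path) -> None:
        """Write W in MatrixMarket coordinate (triplet, 1-based) format."""
        mmwrite(str(path), sp.coo_matrix(self.W), symmetry="symmetric")


def _pairwise_wrapped_dist(coords: Coordinates) -> np.ndarray:
    """Dense pairwise Euclidean distances with torus wrapping. O(n^2); test-scale only."""
    wx, wy = coords.torus_extent
    dx = np.abs(coords.x[:, None] - coords.x[None, :])
    dy = np.abs(coords.y[:, None] - coords.y[None, :])
    dx = np.minimum(dx, wx - dx)
    dy = np.minimum(dy, wy - dy)
    return np.hypot(dx, dy)


def _min_spacing(coords: Coordinates) -> float:
    if coords.torus_extent is not None:
        d = _pairwise_wrapped_dist(coords)
        np.fill_diagonal(d, np.inf)
        return float(d.min())
    tree = cKDTree(coords.xy)
    dist, _ = tree.query(coords.xy, k=2)
    return float(dist[:, 1].min())


def build_grid_weights(coords: Coordinates, n_neighbors: int = 8) -> WeightMatrix:
    """Unit weights between lattice neighbours.

    The lattice unit is the smallest pairwise spot distance; two spots are
    neighbours iff their distance is at most 1.5 lattice units.  On a square
    grid this yields the 8-neighbourhood (diagonals sit at sqrt(2) units);
    on a hexagonal layout, the 6-neighbourhood.  Border spots simply have
    fewer neighbours.  Incomplete lattices (holes) are allowed.
    """
    if coords.n < 2:
        raise ValueError("need at least 2 spots")
    unit = _min_spacing(coords)
    if unit <= 0:
        raise ValueError("duplicate spot coordinates")
    cutoff = 1.5 * unit
    if coords.torus_extent is not None:
        d = _pairwise_wrapped_dist(coords)
        np.fill_diagonal(d, np.inf)
        rows, cols = np.nonzero(d <= cutoff)
        W = sp.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(coords.n, coords.n)
        )
    else:
        tree = cKDTree(coords.xy)
        pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
        if pairs.size == 0:
            raise ValueError("empty weight matrix: all spots are isolated")
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        W = sp.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(coords.n, coords.n)
        )
    return WeightMatrix(W, n_neighbors=n_neighbors, kernel="grid8")


def _knn_indices(coords: Coordinates, k: int) -> list[np.ndarray]:
    """Exact k nearest neighbours per spot, ties broken toward the smaller row index.

    Self (distance 0) is never a neighbour.
    """
    tree = cKDTree(coords.xy)
    dist_k, _ = tree.query(coords.xy, k=k + 1)
    out = []
    for i in range(coords.n):
        r = dist_k[i, -1]
        cand = tree.query_ball_point(coords.xy[i], r=r * (1 + 1e-12))
        cand = np.array([j for j in cand if j != i])
        d = np.hypot(
            coords.x[cand] - coords.x[i], coords.y[cand] - coords.y[i]
        )
        order = np.lexsort((cand, d))  # distance first, then row index
        out.append(cand[order[:k]])
    return out


def build_knn_weights(coords: Coordinates, n_neighbors: int = 8) -> WeightMatrix:
    """Symmetrized k-nearest-neighbour graph with unit directed weights.

    The directed adjacency (w_ij = 1 iff j is among i's N nearest
    neighbours) is symmetrized as W = (W' + W'^T)/2, so entries are 1 for
    mutual neighbours and 1/2 for one-sided ones.
    """
    if coords.n <= n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={n_neighbors} spots, got {coords.n}"
        )
    nbrs = _knn_indices(coords, n_neighbors)
    rows = np.repeat(np.arange(coords.n), [len(v) for v in nbrs])
    cols = np.concatenate(nbrs)
    Wd = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(coords.n, coords.n)
    )
    W = (Wd + Wd.T) * 0.5
    return WeightMatrix(W, n_neighbors=n_neighbors, kernel="knn_uniform")


def _perplexity(w: np.ndarray) -> float:
    w = w[w > 0]
    return float(2 ** (-(w * np.log2(w)).sum()))


def _calibrate_sigma(
    d: np.ndarray, perplexity: float, tol: float = 1e-5, max_iter: int = 200
) -> tuple[float, np.ndarray]:
    """Bisect the kernel width so the normalized weights hit the target perplexity.

    Perp(sigma) is monotone increasing in sigma, from 1 (only the nearest
    neighbour) towards the number of neighbours (equal weights).
    """

    if d.max() - d.min() <= 1e-12 * max(d.max(), 1.0):
        # all neighbours equidistant: weights are uniform for every sigma
        # (the maximum-entropy case); the perplexity equation has no other
        # solution, so return the uniform row directly
        return float(np.median(d)), np.full(d.size, 1.0 / d.size)

    def weights(sigma: float) -> np.ndarray:
        e = -(d**2) / (2 * sigma**2)
        a = np.exp(e - e.max())  # log-domain shift avoids total underflow
        return a / a.sum()

    lo = hi = float(np.median(d)) or 1.0
    for _ in range(60):
        if _perplexity(weights(lo)) < perplexity:
            break
        lo /= 2.0
    for _ in range(60):
        if _perplexity(weights(hi)) > perplexity:
            break
        hi *= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = _perplexity(weights(mid))
        if abs(p - perplexity) < tol:
            return mid, weights(mid)
        if p < perplexity:
            lo = mid
        else:
            hi = mid
    p = _perplexity(weights(0.5 * (lo + hi)))
    if abs(p - perplexity) < 10 * tol:
        return 0.5 * (lo + hi), weights(0.5 * (lo + hi))
    raise RuntimeError(
        f"perplexity bisection did not converge: target {perplexity}, "
        f"reached {p} with sigma in [{lo}, {hi}]"
    )


def build_gaussian_weights(
    coords: Coordinates, n_neighbors: int = 8, perplexity: float = 4.0
) -> WeightMatrix:
    """Gaussian-kernel weights over each spot's N nearest neighbours.

    Per spot i, w_ij = K_i exp(-||x_i - x_j||^2 / (2 sigma_i^2)) over the N
    nearest neighbours, normalized to sum 1, with sigma_i chosen by
    bisection so the perplexity 2^H of the weight row equals ``perplexity``.
    The directed matrix is symmetrized as W = (W' + W'^T)/2.
    """
    if not (1.0 < perplexity < n_neighbors):
        raise ValueError(
            f"perplexity must lie in (1, n_neighbors={n_neighbors}), got {perplexity}"
        )
    if coords.n <= n_neighbors:
        raise ValueError("need more than n_neighbors spots")
    nbrs = _knn_indices(coords, n_neighbors)
    rows, cols, vals = [], [], []
    for i, idx in enumerate(nbrs):
        d = np.hypot(coords.x[idx] - coords.x[i], coords.y[idx] - coords.y[i])
        _, w = _calibrate_sigma(d, perplexity)
        rows.extend([i] * len(idx))
        cols.extend(idx.tolist())
        vals.extend(w.tolist())
    Wd = sp.csr_matrix((vals, (rows, cols)), shape=(coords.n, coords.n))
    W = (Wd + Wd.T) * 0.5
    return WeightMatrix(W, n_neighbors=n_neighbors, kernel="gaussian_perplexity")
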