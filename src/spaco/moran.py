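"""The Moran operator L, its scalar product, and the univariate spatial statistics.

For a centred pattern x scaled to population variance 1 on n spots with
weight matrix W (total weight |W|), Moran's I and Geary's C are

    I(x) = (1/|W|) sum_ij w_ij x_i x_j
    C(x) = (1/(2|W|)) sum_ij w_ij (x_i - x_j)^2

Both are invariant under rescaling W.  The operator

    L = (1/n) E + (1/|W|) W

(E the identity) induces the positive semidefinite scalar product
<x, y>_L = x^T L y, whose key property is that for centred, unit-variance
patterns the squared L-norm equals 1 + I(x): spatially smooth patterns are
*long* in this geometry, non-spatial ones short.  L is kept in structured
form (scaled identity plus scaled sparse W) and never densified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .weights import WeightMatrix

__all__ = ["MoranOperator", "center_scale", "morans_I", "gearys_C", "l_inner"]


def center_scale(x: np.ndarray) -> np.ndarray:
    """Centre to mean 0 and scale to population variance 1 (divide by n).

    The population convention is what makes x^T L x = 1 + I(x) exact:
    (1/n) x^T x must equal 1.
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    var = float(xc @ xc) / x.shape[0]
    if var < 1e-18 * max(1.0, float(np.abs(x).max()) ** 2):
        raise ValueError("zero-variance feature cannot be centred and scaled")
    return xc / np.sqrt(var)


def _as_sparse(W) -> tuple[sp.csr_matrix, float]:
    if isinstance(W, WeightMatrix):
        return W.W, W.total_weight
    W = sp.csr_matrix(W)
    return W, float(W.sum())


def morans_I(x: np.ndarray, W) -> float:
    """Moran's I of a centred, unit-variance pattern: (1/|W|) x^T W x.

    Computed directly from W (not via L) to avoid cancellation.
    """
    Wm, tw = _as_sparse(W)
    x = np.asarray(x, dtype=float)
    if x.shape[0] != Wm.shape[0]:
        raise ValueError("pattern length does not match weight matrix size")
    return float(x @ (Wm @ x)) / tw


def gearys_C(x: np.ndarray, W) -> float:
    """Geary's C of a centred, unit-variance pattern: (1/(2|W|)) sum w_ij (x_i-x_j)^2."""
    Wm, tw = _as_sparse(W)
    x = np.asarray(x, dtype=float)
    if x.shape[0] != Wm.shape[0]:
        raise ValueError("pattern length does not match weight matrix size")
    deg = np.asarray(Wm.sum(axis=1)).ravel()
    # sum w_ij (x_i - x_j)^2 = 2 x^T D x - 2 x^T W x with D = diag(row sums)
    return float(x @ (deg * x) - x @ (Wm @ x)) / tw


@dataclass
class MoranOperator:
    """L = (1/n) E + (1/|W|) W, held as scaled-sparse-plus-scaled-identity."""

    W: sp.csr_matrix
    n: int
    total_weight: float

    @classmethod
    def from_weights(cls, weights: WeightMatrix) -> "MoranOperator":
        return cls(W=weights.W, n=weights.n, total_weight=weights.total_weight)

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """L @ x for a vector or (n, m) matrix of column patterns."""
        x = np.asarray(x, dtype=float)
        if x.shape[0] != self.n:
            raise ValueError("operand has wrong number of spots")
        return x / self.n + (self.W @ x) / self.total_weight

    __matmul__ = matvec

    def quadratic_form(self, X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
        """X^T L Y (Y defaults to X), without densifying L."""
        if Y is None:
            Y = X
        return np.asarray(X).T @ self.matvec(Y)

    def dense(self) -> np.ndarray:
        """Dense L, for small-n oracle checks only."""
        if self.n > 1000:
            raise ValueError("refusing to densify L for n > 1000")
        return np.eye(self.n) / self.n + self.W.toarray() / self.total_weight


def l_inner(x: np.ndarray, y: np.ndarray, L: MoranOperator) -> float:
    """The scalar product <x, y>_L = x^T L y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != L.n or y.shape[0] != L.n:
        raise ValueError("vector length does not match operator size")
    return float(x @ L.matvec(y))
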