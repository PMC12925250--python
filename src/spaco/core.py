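"""The spatial-component eigenproblem, permutation selection, and projection.

Spatial component analysis performs a PCA of the whitened data Xw with
respect to the scalar product <.,.>_L: the spatial components u_i are the
eigenvectors of the q x q matrix Xw^T L Xw, sorted by decreasing eigenvalue
lambda_i.  Because Xw is whitened, every unit-norm combination u yields a
pattern Xw u with population variance 1, so

    u^T (Xw^T L Xw) u = 1 + I(Xw u)

and the leading eigenvector maximizes Moran's I over all unit combinations;
by Courant-Fischer, the span of the first k patterns maximizes the worst
Moran's I over all k-dimensional subspaces of the pattern space.

The number k of components carrying real spatial signal is chosen by a
permutation test on the *largest* eigenvalue: permuting the spots of Xw
destroys all spatial structure while preserving the covariance, so the
largest eigenvalue of the permuted problem is the natural null for every
observed eigenvalue simultaneously — thresholding at its conservative
(1 - gamma) empirical quantile controls the family-wise error rate at
gamma.

The L-orthonormalized patterns s_i = Xw u_i / sqrt(lambda_i) provide the
L-orthogonal projection P(Y) = sum_{i<=k} <s_i, Y>_L s_i used for denoising
and for the spatially-variable-gene statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .moran import MoranOperator
from .preprocess import WhitenedData

__all__ = ["SpacoModel", "fit_spacs", "permutation_null", "select_components",
           "project"]

_EIG_TOL = 1e-10


@dataclass
class SpacoModel:
    """Fitted spatial components.

    ``components`` holds the eigenvectors u_i (columns, unit Euclidean norm
    in whitened space), ``patterns`` the spot-space patterns v_i = Xw u_i,
    and ``orthonormal_patterns`` the L-orthonormal s_i = v_i / sqrt(lambda_i)
    for all eigenvalues above numerical zero.  After selection, ``k`` is the
    number of significant components, ``threshold`` the permutation-null
    quantile they were compared against, and ``null_sample`` the raw
    permutation draws.
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    patterns: np.ndarray
    orthonormal_patterns: np.ndarray
    gene_loadings: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    k: int | None = None
    threshold: float | None = None
    fwer: float | None = None
    null_sample: np.ndarray | None = None
    seed: int | None = None

    @property
    def q(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def n_spots(self) -> int:
        return self.patterns.shape[0]

    @property
    def is_selected(self) -> bool:
        return self.k is not None

    @property
    def S_k(self) -> np.ndarray:
        """The n x k matrix of selected L-orthonormal patterns."""
        if self.k is None:
            raise ValueError("model has no selected components; run select_components")
        return self.orthonormal_patterns[:, : self.k]


def _cross_product(Xw: np.ndarray, L: MoranOperator) -> np.ndarray:
    A = Xw.T @ L.matvec(Xw)
    return (A + A.T) / 2.0


def fit_spacs(Xw: WhitenedData, L: MoranOperator) -> SpacoModel:
    """Solve the q x q eigenproblem Xw^T L Xw and assemble the model.

    The eigenproblem is always solved in the whitened component space
    (q x q, q at most a few hundred); L enters only through quadratic
    forms and is never densified.  Component signs are fixed so the loading
    of largest absolute value is positive.
    """
    if Xw.n_spots != L.n:
        raise ValueError(
            f"whitened data has {Xw.n_spots} spots but operator has {L.n}"
        )
    M = _cross_product(Xw.Xw, L)
    lam, U = np.linalg.eigh(M)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    U = U[:, order]
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    U = U * flip
    V = Xw.Xw @ U
    pos = lam > _EIG_TOL
    S = V[:, pos] / np.sqrt(lam[pos])
    return SpacoModel(
        eigenvalues=lam,
        components=U,
        patterns=V,
        orthonormal_patterns=S,
        gene_loadings=Xw.rotation @ U,
        spot_ids=list(Xw.spot_ids),
        gene_ids=list(Xw.gene_ids),
    )


def permutation_null(
    Xw: WhitenedData,
    L: MoranOperator,
    R: int = 1000,
    seed: int | None = None,
    subsample: int | None = None,
) -> np.ndarray:
    """R draws of the largest eigenvalue under uniform spot permutation.

    Each draw permutes the rows (spots) of Xw and records the largest
    eigenvalue of the permuted Xw^T L Xw; W and L stay fixed.

    ``subsample`` restricts every draw to a fixed random subset of spots
    (with the weight matrix cut down accordingly).  This is an UNCALIBRATED
    speed heuristic for very large slides: the resulting threshold has no
    family-wise error guarantee for the full-data eigenvalues.
    """
    if R < 100:
        raise ValueError("R must be at least 100 for a stable 5% quantile")
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    if Xw.n_spots != L.n:
        raise ValueError("spot-count mismatch between whitened data and operator")
    rng = np.random.default_rng(seed)
    X = Xw.Xw
    W = L.W
    n = X.shape[0]
    if subsample is not None:
        if not (1 < subsample < n):
            raise ValueError("subsample must be in (1, n_spots)")
        import warnings

        warnings.warn(
            "spot-subsampled permutation null is an uncalibrated speed "
            "heuristic; thresholds from it carry no error guarantee",
            stacklevel=2,
        )
        idx = np.sort(rng.choice(n, size=subsample, replace=False))
        X = X[idx]
        W = W[idx][:, idx].tocsr()
        n = subsample
    total_weight = float(W.sum())
    if total_weight <= 0:
        raise ValueError("subsampled weight matrix is empty")
    out = np.empty(R)
    for r in range(R):
        Xp = X[rng.permutation(n)]
        M = Xp.T @ (Xp / n + (W @ Xp) / total_weight)
        M = (M + M.T) / 2.0
        out[r] = np.linalg.eigvalsh(M)[-1]
    return out


def select_components(
    model: SpacoModel, null_sample: np.ndarray, fwer: float = 0.05
) -> SpacoModel:
    """Threshold the eigenvalues at the conservative empirical null quantile.

    The threshold is the order statistic of rank ceil((R + 1)(1 - gamma)) of
    the R permutation draws, which guarantees P(max-null-eigenvalue > l) <=
    gamma for the empirical null (the direction the family-wise error
    guarantee needs); interpolated quantiles do not.  k = 0 is a legal
    outcome meaning no spatial structure was detected.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    if not (0 < fwer < 1):
        raise ValueError("fwer must be in (0, 1)")
    R = null_sample.size
    rank = math.ceil((R + 1) * (1 - fwer))
    if rank > R:
        threshold = np.inf  # too few permutations to certify this gamma
    else:
        threshold = float(np.sort(null_sample)[rank - 1])
    k = int((model.eigenvalues > threshold).sum())
    k = min(k, model.orthonormal_patterns.shape[1])
    return replace(
        model, k=k, threshold=threshold, fwer=fwer, null_sample=null_sample
    )


def project(Y: np.ndarray, model: SpacoModel, L: MoranOperator) -> np.ndarray:
    """L-orthogonal projection of patterns onto the selected component span.

    ``Y`` is an n-vector or n x m matrix of centred, scaled patterns;
    returns sum_{i<=k} (s_i^T L Y) s_i.  Projections are spatial by
    construction for *any* input, so this should only be applied to
    patterns established as significantly spatial.
    """
    if model.k is None:
        raise ValueError("model has no selected components; run select_components")
    if model.k == 0:
        raise ValueError("no significant spatial components; projection undefined")
    Y = np.asarray(Y, dtype=float)
    S = model.S_k
    if Y.shape[0] != S.shape[0]:
        raise ValueError("pattern length does not match model")
    return S @ (S.T @ L.matvec(Y))
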