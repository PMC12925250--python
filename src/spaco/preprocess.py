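"""Gene-wise z-transformation and PCA whitening.

The eigenproblem downstream assumes the data have identity covariance, so
whitening is an indispensable preprocessing step: after gene-wise centring
and scaling, the data are rotated into principal-component space and each
component is rescaled to unit (population) variance.  Only the smallest
number of components retaining at least 95% of the variance is kept.

Input matrices are assumed normalized upstream (e.g. by SCTransform or any
variance-stabilizing normalization appropriate to the modality).  A simple
library-size + log1p helper is provided for convenience and is never
applied silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "WhitenedData", "z_transform", "pca_whiten",
           "log_normalize"]


@dataclass
class ExpressionMatrix:
    """A spots x genes matrix with identifiers.

    ``layer`` records the processing state: raw ``counts``, ``normalized``
    (variance-stabilized, ready for z-transformation), or ``scaled``
    (gene-wise mean 0, population variance 1).  ``dropped_genes`` lists
    genes removed as zero-variance during scaling, so they can be reported
    as NA in downstream tables rather than silently vanishing.
    """

    X: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    layer: str = "counts"
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sp.issparse(self.X):
            self.X = np.asarray(self.X.todense())
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n, p = self.X.shape
        if len(self.spot_ids) != n or len(self.gene_ids) != p:
            raise ValueError(
                f"id lists ({len(self.spot_ids)} spots, {len(self.gene_ids)} genes) "
                f"do not match matrix shape {self.X.shape}"
            )
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot ids")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene ids")
        if not np.isfinite(self.X).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.layer == "counts" and self.X.min() < 0:
            raise ValueError("negative values in a counts matrix")

    @property
    def n_spots(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]


@dataclass
class WhitenedData:
    """Spots x components matrix with identity (population) covariance.

    ``rotation`` maps gene space to component space, ``Xw = X_scaled @ rotation``,
    so component loadings can be pulled back to genes.
    """

    Xw: np.ndarray
    q: int
    variance_retained: float
    rotation: np.ndarray
    eigenvalues: np.ndarray
    eigenvalues_dropped: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]

    @property
    def n_spots(self) -> int:
        return self.Xw.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Xw, index=self.spot_ids,
            columns=[f"PC{i + 1}" for i in range(self.q)],
        )


def log_normalize(X: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalization followed by log1p, as a convenience only.

    This is a crude stand-in for a proper variance-stabilizing
    normalization (e.g. Pearson residuals); it is provided so raw counts
    can be pushed through the pipeline, and it always logs a warning.
    """
    if X.layer != "counts":
        raise ValueError(f"log_normalize expects counts, got layer={X.layer!r}")
    logger.warning(
        "log_normalize is a convenience; for real data prefer a dedicated "
        "variance-stabilizing normalization before spatial analysis"
    )
    totals = X.X.sum(axis=1)
    totals[totals == 0] = 1.0
    Xn = np.log1p(X.X / totals[:, None] * scale)
    return ExpressionMatrix(Xn, X.spot_ids, X.gene_ids, layer="normalized")


def z_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Centre every gene to mean 0 and scale to population variance 1.

    Zero-variance genes cannot be scaled; they are dropped with a warning
    and recorded in ``dropped_genes``.
    """
    if X.layer != "normalized":
        raise ValueError(f"z_transform expects normalized data, got layer={X.layer!r}")
    mu = X.X.mean(axis=0)
    Xc = X.X - mu
    var = (Xc**2).mean(axis=0)
    scale_ref = np.maximum(1.0, np.abs(X.X).max(axis=0) ** 2)
    keep = var >= 1e-18 * scale_ref
    if not keep.any():
        raise ValueError("all genes are constant; nothing to scale")
    dropped = [g for g, k in zip(X.gene_ids, keep) if not k]
    if dropped:
        logger.warning("dropping %d zero-variance gene(s): %s",
                       len(dropped), ", ".join(dropped[:10]))
    Xs = Xc[:, keep] / np.sqrt(var[keep])
    return ExpressionMatrix(
        Xs, X.spot_ids, [g for g, k in zip(X.gene_ids, keep) if k],
        layer="scaled", dropped_genes=list(X.dropped_genes) + dropped,
    )


def pca_whiten(X: ExpressionMatrix, variance_threshold: float = 0.95) -> WhitenedData:
    """PCA-whiten a scaled matrix, keeping the fewest components with >= 95% variance.

    From the SVD ``X = U S V^T`` the whitened matrix is ``sqrt(n) U_q``: its
    columns have mean zero and its population covariance is the q x q
    identity.  Components with singular value below 1e-10 of the largest
    are treated as numerical rank deficiency and excluded before the
    variance threshold is applied.
    """
    if X.layer != "scaled":
        raise ValueError(f"pca_whiten expects scaled data, got layer={X.layer!r}")
    if not (0 < variance_threshold <= 1):
        raise ValueError("variance_threshold must be in (0, 1]")
    n, p = X.X.shape
    if n < 2:
        raise ValueError("need at least 2 spots")
    U, s, Vt = np.linalg.svd(X.X, full_matrices=False)
    nonzero = s > 1e-10 * s[0] if s[0] > 0 else np.zeros_like(s, bool)
    if not nonzero.any():
        raise ValueError("rank-0 expression matrix cannot be whitened")
    s = s[nonzero]
    U = U[:, nonzero]
    Vt = Vt[nonzero]
    ev = s**2 / n  # population eigenvalues of the gene-gene covariance
    frac = np.cumsum(ev) / ev.sum()
    q = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    Xw = np.sqrt(n) * U[:, :q]
    rotation = np.sqrt(n) * (Vt[:q].T / s[:q])
    return WhitenedData(
        Xw=Xw, q=q, variance_retained=float(frac[q - 1]),
        rotation=rotation, eigenvalues=ev[:q], eigenvalues_dropped=ev[q:],
        spot_ids=list(X.spot_ids), gene_ids=list(X.gene_ids),
    )
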