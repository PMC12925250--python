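"""End-to-end convenience: normalized matrix + coordinates -> selected model."""

from __future__ import annotations

from .core import SpacoModel, fit_spacs, permutation_null, select_components
from .moran import MoranOperator
from .preprocess import ExpressionMatrix, WhitenedData, pca_whiten, z_transform
from .weights import (
    Coordinates,
    build_gaussian_weights,
    build_grid_weights,
    build_knn_weights,
)

__all__ = ["fit_pipeline"]

_BUILDERS = {
    "grid8": build_grid_weights,
    "knn_uniform": build_knn_weights,
    "gaussian_perplexity": build_gaussian_weights,
}


def fit_pipeline(
    X: ExpressionMatrix,
    coords: Coordinates,
    seed: int,
    *,
    kernel: str = "grid8",
    n_neighbors: int = 8,
    perplexity: float = 4.0,
    variance_threshold: float = 0.95,
    permutations: int = 1000,
    fwer: float = 0.05,
) -> tuple[SpacoModel, MoranOperator, WhitenedData]:
    """z-transform, whiten, build weights, fit, and select components.

    ``X`` must be a ``normalized`` (or already ``scaled``) matrix whose spot
    order matches ``coords``.  Returns the selected model, the Moran
    operator, and the whitened data.
    """
    if kernel not in _BUILDERS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {sorted(_BUILDERS)}")
    if X.n_spots != coords.n:
        raise ValueError("matrix and coordinates have different numbers of spots")
    if kernel == "gaussian_perplexity":
        weights = _BUILDERS[kernel](coords, n_neighbors, perplexity)
    else:
        weights = _BUILDERS[kernel](coords, n_neighbors)
    L = MoranOperator.from_weights(weights)
    Xs = X if X.layer == "scaled" else z_transform(X)
    Xw = pca_whiten(Xs, variance_threshold)
    model = fit_spacs(Xw, L)
    null = permutation_null(Xw, L, R=permutations, seed=seed)
    model = select_components(model, null, fwer=fwer)
    model.seed = seed
    return model, L, Xw
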