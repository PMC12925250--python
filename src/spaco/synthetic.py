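"""Synthetic lattice datasets with controllable spatial dependence.

Stands in for real spatial transcriptomics slides in every test: spots on
a unit-spaced rectangular lattice, gene patterns mixing a Gaussian-smoothed
random field (the spatial signal) with fresh white noise.  The mixing
weight alpha interpolates from pure noise (alpha = 0, Moran's I near its
permutation-null expectation -1/(n-1)) to a fully smooth field (alpha = 1);
expected Moran's I increases monotonically in alpha, which is the only
property downstream experiments rely on.

Counts are generated per gene as Poisson(coverage_mean * softplus(x) /
mean(softplus(x))), giving mild coverage heterogeneity; a ``gaussian``
count model instead emits the standardized values directly as a
``normalized`` layer, for experiments whose null is i.i.d. standard normal
spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocess import ExpressionMatrix
from .weights import Coordinates

__all__ = ["SyntheticSpec", "make_lattice", "simulate_pattern", "simulate_dataset"]


@dataclass
class SyntheticSpec:
    """Dataset recipe: lattice size, gene counts, signal shape and strength."""

    n_rows: int = 12
    n_cols: int = 12
    n_spatial_genes: int = 30
    n_noise_genes: int = 470
    smoothness: float = 3.0
    signal_fraction: float = 0.8
    coverage_mean: float = 50.0
    seed: int = 0
    torus: bool = False
    n_latents: int = 3
    count_model: str = "poisson"

    def __post_init__(self) -> None:
        if self.n_rows < 4 or self.n_cols < 4:
            raise ValueError("lattice dimensions must be at least 4")
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise ValueError("signal_fraction must be in [0, 1]")
        if self.count_model not in ("poisson", "gaussian"):
            raise ValueError("count_model must be 'poisson' or 'gaussian'")


def make_lattice(n_rows: int, n_cols: int, torus: bool = False) -> Coordinates:
    """Unit-spaced rectangular lattice, row-major order; x = column, y = row."""
    if n_rows < 2 or n_cols < 2:
        raise ValueError("lattice dimensions must be at least 2")
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    ids = [f"s{r:03d}_{c:03d}" for r, c in zip(rr.ravel(), cc.ravel())]
    return Coordinates(
        spot_ids=ids,
        x=cc.ravel().astype(float),
        y=rr.ravel().astype(float),
        torus_extent=(float(n_cols), float(n_rows)) if torus else None,
    )


def _lattice_shape(coords: Coordinates) -> tuple[int, int]:
    n_rows = np.unique(coords.y).size
    n_cols = np.unique(coords.x).size
    if n_rows * n_cols != coords.n:
        raise ValueError("coordinates do not form a complete rectangular lattice")
    return n_rows, n_cols


def _standardize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    sd = np.sqrt((v**2).mean())
    return v / sd if sd > 0 else v


def _smooth_field(
    coords: Coordinates, smoothness: float, rng: np.random.Generator
) -> np.ndarray:
    n_rows, n_cols = _lattice_shape(coords)
    field = rng.standard_normal((n_rows, n_cols))
    if smoothness > 0:
        mode = "wrap" if coords.torus_extent is not None else "reflect"
        field = gaussian_filter(field, sigma=smoothness, mode=mode)
    # map back through the coordinate order (row-major from make_lattice)
    idx = (coords.y.astype(int) * n_cols + coords.x.astype(int))
    return _standardize(field.ravel()[idx])


def simulate_pattern(
    coords: Coordinates,
    smoothness: float,
    signal_fraction: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One centred, unit-variance pattern: alpha * smooth field + (1 - alpha) * noise."""
    if smoothness < 0:
        raise ValueError("smoothness must be non-negative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    f = _smooth_field(coords, smoothness, rng)
    eps = _standardize(rng.standard_normal(coords.n))
    return _standardize(signal_fraction * f + (1.0 - signal_fraction) * eps)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, Coordinates, np.ndarray]:
    """A full dataset: counts (or gaussian values), coordinates, truth labels.

    Spatial genes share ``n_latents`` latent smooth fields (cycled) with
    gene-specific noise at the spec's signal fraction; noise genes are pure
    white noise.  Returns (matrix, coordinates, boolean truth per gene).
    """
    rng = np.random.default_rng(spec.seed)
    coords = make_lattice(spec.n_rows, spec.n_cols, torus=spec.torus)
    n = coords.n
    p = spec.n_spatial_genes + spec.n_noise_genes
    if p == 0:
        raise ValueError("dataset must contain at least one gene")
    n_lat = max(1, min(spec.n_latents, spec.n_spatial_genes or 1))
    latents = [_smooth_field(coords, spec.smoothness, rng) for _ in range(n_lat)]
    cols = []
    for g in range(spec.n_spatial_genes):
        eps = _standardize(rng.standard_normal(n))
        cols.append(_standardize(
            spec.signal_fraction * latents[g % n_lat]
            + (1.0 - spec.signal_fraction) * eps
        ))
    for _ in range(spec.n_noise_genes):
        cols.append(rng.standard_normal(n))
    Z = np.column_stack(cols)
    truth = np.arange(p) < spec.n_spatial_genes
    gene_ids = [
        f"svg{g:04d}" if truth[g] else f"noise{g - spec.n_spatial_genes:04d}"
        for g in range(p)
    ]
    if spec.count_model == "gaussian":
        X = ExpressionMatrix(Z, coords.spot_ids, gene_ids, layer="normalized")
        return X, coords, truth
    sp_ = _softplus(Z)
    rates = spec.coverage_mean * sp_ / sp_.mean(axis=0)
    counts = rng.poisson(rates).astype(float)
    X = ExpressionMatrix(counts, coords.spot_ids, gene_ids, layer="counts")
    return X, coords, truth
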