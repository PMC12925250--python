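"""Coverage-adjusted local resampling: noise injection and negative controls.

Local resampling progressively destroys the spatial signal of expression
patterns while preserving each gene's abundance distribution: every spot
redraws its value from a uniformly chosen donor spot within radius ``r``
(``r = inf`` destroys the signal entirely and serves as the negative
control, a gene's non-spatial "twin").  Because raw resampling induces an
artificial anticorrelation with the per-spot coverage pattern — itself
spatially structured — the resampled matrix is rescaled afterwards so each
spot keeps its original total coverage exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .preprocess import ExpressionMatrix
from .weights import Coordinates

__all__ = ["ResamplingConfig", "local_resample", "make_twin_controls"]


@dataclass
class ResamplingConfig:
    """Radius (coordinate units; ``inf`` = unrestricted), seed, and donor policy.

    ``per_gene=True`` draws an independent donor per gene and spot (each
    gene's pattern is perturbed independently); ``per_gene=False`` draws one
    donor per spot shared by all genes.
    """

    radius: float
    seed: int
    include_self: bool = True
    per_gene: bool = True

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError("radius must be positive (use inf for unrestricted)")


def _neighbourhoods(
    coords: Coordinates, radius: float, include_self: bool
) -> list[np.ndarray]:
    n = coords.n
    if math.isinf(radius):
        all_spots = np.arange(n)
        return [
            all_spots if include_self else np.delete(all_spots, i)
            for i in range(n)
        ]
    tree = cKDTree(coords.xy)
    hoods = tree.query_ball_point(coords.xy, r=radius * (1 + 1e-12))
    out = []
    for i, h in enumerate(hoods):
        h = np.asarray(sorted(h))
        if not include_self:
            h = h[h != i]
        if h.size == 0:
            raise ValueError(
                f"spot {coords.spot_ids[i]!r} has an empty neighbourhood at "
                f"radius {radius} with include_self={include_self}"
            )
        out.append(h)
    return out


def local_resample(
    counts: ExpressionMatrix, coords: Coordinates, cfg: ResamplingConfig
) -> ExpressionMatrix:
    """Redraw every spot's values from donors within the radius, coverage-adjusted.

    After resampling, each spot's row is multiplied by (original spot total
    / resampled spot total), so per-spot coverage is preserved exactly;
    spots whose resampled total is zero keep their zeros.  Values stay
    continuous (no re-rounding to integers).
    """
    if counts.n_spots != coords.n:
        raise ValueError("counts and coordinates have different numbers of spots")
    if counts.X.min() < 0:
        raise ValueError("resampling expects non-negative values")
    rng = np.random.default_rng(cfg.seed)
    hoods = _neighbourhoods(coords, cfg.radius, cfg.include_self)
    n, p = counts.X.shape
    donors = np.empty((n, p if cfg.per_gene else 1), dtype=np.int64)
    for i, h in enumerate(hoods):
        donors[i] = h[rng.integers(0, h.size, size=donors.shape[1])]
    if cfg.per_gene:
        Xr = counts.X[donors, np.arange(p)[None, :]]
    else:
        Xr = counts.X[donors[:, 0]]
    orig_tot = counts.X.sum(axis=1)
    new_tot = Xr.sum(axis=1)
    scale = np.divide(orig_tot, new_tot, out=np.zeros(n), where=new_tot > 0)
    return ExpressionMatrix(
        Xr * scale[:, None], counts.spot_ids, counts.gene_ids, layer=counts.layer
    )


def make_twin_controls(
    counts: ExpressionMatrix,
    genes: list[str],
    coords: Coordinates,
    seed: int,
) -> ExpressionMatrix:
    """Append a coverage-adjusted, unrestricted-resampling "twin" per listed gene.

    Each twin redraws the gene's value at spot i from a uniformly chosen
    donor spot (with replacement, self included) and multiplies it by the
    coverage ratio cov_i / cov_donor, where cov is the spot's total count
    over all genes — so the twin carries no spatial signal beyond what the
    coverage pattern itself imposes, mirroring the adjustment applied by
    the full-matrix resampler.  Twins are named ``<gene>_twin``.
    """
    if counts.n_spots != coords.n:
        raise ValueError("counts and coordinates have different numbers of spots")
    index = {g: j for j, g in enumerate(counts.gene_ids)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise ValueError(f"unknown gene id(s): {', '.join(missing)}")
    rng = np.random.default_rng(seed)
    n = counts.n_spots
    cov = counts.X.sum(axis=1)
    twins = []
    for g in genes:
        donor = rng.integers(0, n, size=n)
        ratio = np.divide(cov, cov[donor], out=np.zeros(n), where=cov[donor] > 0)
        twins.append(counts.X[donor, index[g]] * ratio)
    Xa = np.column_stack([counts.X] + twins)
    return ExpressionMatrix(
        Xa,
        counts.spot_ids,
        list(counts.gene_ids) + [f"{g}_twin" for g in genes],
        layer=counts.layer,
    )
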