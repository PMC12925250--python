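"""Spatially-variable-gene testing against a weighted-chi-square null.

The statistic for a gene pattern x (centred, population variance 1) is the
squared L-norm of its projection onto the selected spatial components,

    t = ||P(x)||_L^2 = sum_{i<=k} (s_i^T L x)^2 = x^T Sigma x,
    Sigma = L^T S_k S_k^T L.

Under the null that the spots of x are i.i.d. standard normal, t is a
weighted sum of independent chi-square(1) variables whose non-zero weights
c_1..c_k are the eigenvalues of the small k x k matrix
Sigma~ = (S_k^T L)(L S_k).  One-sided p-values P(T >= t) are computed by
Ruben's expansion of the mixture distribution into a series of central
chi-square survival functions, whose truncation error is controlled by the
unassigned mixture mass; numerical inversion of the characteristic
function (Imhof's method) and a moment-matching (Liu-Tang-Zhang)
noncentral-chi-square approximation serve as fallbacks in the rare cases
where the series converges too slowly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import chdtrc
from scipy.stats import chi2, ncx2
from statsmodels.stats.multitest import multipletests

from .core import SpacoModel
from .moran import MoranOperator
from .preprocess import ExpressionMatrix

__all__ = ["NullCoefficients", "null_coefficients", "svg_statistic",
           "tail_probability", "tail_probabilities", "test_genes"]

P_FLOOR = 1e-300


@dataclass
class NullCoefficients:
    """Weights of the chi-square mixture null: eigenvalues of (S_k^T L)(L S_k)."""

    c: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if (self.c < -1e-10).any():
            raise ValueError("mixture coefficients must be non-negative")
        self.c = np.clip(self.c, 0.0, None)


def null_coefficients(model: SpacoModel, L: MoranOperator) -> NullCoefficients:
    """Eigenvalues of Sigma~ = (S_k^T L)(L S_k), descending, clipped at zero.

    These are exactly the non-zero eigenvalues of the full n x n
    Sigma = L^T S_k S_k^T L (of which there are at most k), but obtained
    from a k x k problem.
    """
    if model.k is None:
        raise ValueError("model has no selected components; run select_components")
    if model.k == 0:
        raise ValueError("no significant spatial components; null undefined")
    B = L.matvec(model.S_k)  # n x k, = L S_k
    sigma_small = B.T @ B
    c = np.linalg.eigvalsh((sigma_small + sigma_small.T) / 2.0)[::-1]
    return NullCoefficients(c=np.clip(c, 0.0, None), k=model.k)


def _check_centred_scaled(x: np.ndarray) -> None:
    n = x.shape[0]
    if abs(float(x.mean())) > 1e-6 or abs(float(x @ x) / n - 1.0) > 1e-4:
        raise ValueError(
            "pattern must be centred to mean 0 and scaled to population variance 1"
        )


def svg_statistic(x: np.ndarray, model: SpacoModel, L: MoranOperator) -> float:
    """t = sum_{i<=k} (s_i^T L x)^2, the squared L-norm of the projected pattern."""
    if model.k is None or model.k == 0:
        raise ValueError("model must have k >= 1 selected components")
    x = np.asarray(x, dtype=float)
    if x.shape[0] != L.n:
        raise ValueError("pattern length does not match operator size")
    _check_centred_scaled(x)
    proj = model.S_k.T @ L.matvec(x)
    return float(proj @ proj)


def _ruben_sf(
    t: float, c: np.ndarray, max_terms: int = 10000, tol: float = 1e-14
) -> float | None:
    """Upper tail of sum c_i chi2(1) at t by Ruben's chi-square series.

    With beta = min(c), the mixture sum c_i chi2(1) has the representation
    sum_j a_j chi2(k + 2j) scaled by beta, with non-negative coefficients
    a_j summing to 1 (computed by the standard recursion through the power
    sums of 1 - beta/c_i).  The survival function is then a convex
    combination of central chi-square tails; truncation error is bounded by
    the unassigned coefficient mass.  Returns None if the series has not
    converged within ``max_terms`` (extreme coefficient spread).
    """
    k = c.size
    beta = float(c.min())
    r = 1.0 - beta / c  # in [0, 1)
    a0 = np.exp(0.5 * float(np.log(beta / c).sum()))
    if a0 == 0.0:  # extreme spread: underflow before the series can start
        return None
    x = t / beta
    a = np.empty(max_terms)
    b = np.empty(max_terms)  # b_j = sum_i r_i^j
    a[0] = a0
    rpow = np.ones(k)
    total = a0
    term = prev_term = a0 * float(chdtrc(k, x))
    sf = term
    for j in range(1, max_terms):
        rpow *= r
        b[j] = float(rpow.sum())
        a[j] = (float(a[1:j] @ b[j - 1:0:-1]) + a0 * b[j]) / (2 * j)
        prev_term, term = term, a[j] * float(chdtrc(k + 2 * j, x))
        sf += term
        total += a[j]
        rest = 1.0 - total  # unassigned coefficient mass (stalls near eps)
        if (
            (rest < 1e-15 or a[j] < 1e-17)
            and term <= prev_term
            and term < tol * max(sf, 1e-300)
        ):
            return float(min(max(sf, 0.0), 1.0))
    return None


def _ruben_coefficients(c: np.ndarray, n_terms: int) -> np.ndarray:
    """First ``n_terms`` mixture coefficients a_j of Ruben's series for beta = min(c)."""
    beta = float(c.min())
    r = 1.0 - beta / c
    a = np.empty(n_terms)
    a[0] = np.exp(0.5 * float(np.log(beta / c).sum()))
    rpow = np.ones(c.size)
    b = np.empty(n_terms)
    for j in range(1, n_terms):
        rpow *= r
        b[j] = float(rpow.sum())
        a[j] = (float(a[1:j] @ b[j - 1:0:-1]) + a[0] * b[j]) / (2 * j)
    return a


def tail_probabilities(t: np.ndarray, c: NullCoefficients | np.ndarray) -> np.ndarray:
    """Vectorized :func:`tail_probability` for many statistics sharing one null.

    Computes the Ruben series coefficients once and reuses them across all
    statistics; per statistic the survival function is a dot product with a
    vector of central chi-square tails.  Falls back to the scalar routine
    for any statistic whose truncated series has not converged.
    """
    coeffs = c.c if isinstance(c, NullCoefficients) else np.asarray(c, dtype=float)
    coeffs = np.atleast_1d(coeffs)
    coeffs = coeffs[coeffs > 0]
    if coeffs.size == 0:
        raise ValueError("all mixture coefficients are zero")
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("statistics must be non-negative")
    coeffs = coeffs[coeffs > 1e-10 * coeffs.max()]
    beta = float(coeffs.min())
    x_max = float(t.max()) / beta
    # enough terms that a_j has decayed and the chi-square tails are past
    # their peak at dof ~ x for every statistic requested
    n_terms = min(50000, max(200, int(x_max / 2) + 100))
    a = _ruben_coefficients(coeffs, n_terms)
    while a[-1] > 1e-17 and n_terms < 50000:
        n_terms = min(50000, n_terms * 2)
        a = _ruben_coefficients(coeffs, n_terms)
    dof = coeffs.size + 2.0 * np.arange(n_terms)
    out = np.empty(t.size)
    ok = a[-1] < 1e-17
    for i, ti in enumerate(t.ravel()):
        if ti == 0:
            out[i] = 1.0
            continue
        if ok:
            terms = a * chdtrc(dof, ti / beta)
            sf = float(terms.sum())
            # truncated series must have entered its decreasing phase
            if terms[-1] <= terms[-2] and terms[-1] < 1e-14 * max(sf, 1e-300):
                out[i] = min(max(sf, P_FLOOR), 1.0)
                continue
        out[i] = tail_probability(float(ti), coeffs)
    return out.reshape(t.shape)


def _imhof_sf(t: float, c: np.ndarray) -> tuple[float, float]:
    """Upper tail of sum c_i chi2(1) at t by Imhof's inversion formula."""

    def integrand(u: np.ndarray) -> np.ndarray:
        cu = np.multiply.outer(c, u)
        theta = 0.5 * np.arctan(cu).sum(axis=0) - 0.5 * t * u
        ln_rho = 0.25 * np.log1p(cu**2).sum(axis=0)
        return np.sin(theta) / (u * np.exp(ln_rho))

    val, err = integrate.quad(
        integrand, 0.0, np.inf, epsabs=1e-12, epsrel=1e-10, limit=500
    )
    return 0.5 + val / np.pi, err


def _ltz_sf(t: float, c: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matching noncentral-chi-square tail approximation."""
    c1, c2, c3, c4 = (float((c**j).sum()) for j in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    tstar = (t - c1) / np.sqrt(2 * c2)
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        a = 1.0 / s1
        delta = 0.0
        dof = a**2
    mu = dof + delta
    sigma = np.sqrt(2 * (dof + 2 * delta))
    z = tstar * sigma + mu
    if delta > 0:
        return float(ncx2.sf(z, df=dof, nc=delta))
    return float(chi2.sf(z, df=dof))


def tail_probability(t: float, c: NullCoefficients | np.ndarray) -> float:
    """P(sum c_i chi2(1) >= t), floored at 1e-300.

    Ruben's series is exact at any tail depth whenever the coefficient
    spread lets it converge (always the case in practice after discarding
    coefficients below 1e-10 of the largest, which contribute nothing to
    the distribution).  If it does not converge, Imhof quadrature covers
    moderate tails and the moment-matching approximation the far tail.
    """
    coeffs = c.c if isinstance(c, NullCoefficients) else np.asarray(c, dtype=float)
    coeffs = np.atleast_1d(coeffs)
    coeffs = coeffs[coeffs > 0]
    if coeffs.size == 0:
        raise ValueError("all mixture coefficients are zero")
    if t < 0:
        raise ValueError("statistic must be non-negative")
    if t == 0:
        return 1.0
    coeffs = coeffs[coeffs > 1e-10 * coeffs.max()]
    p = _ruben_sf(t, coeffs)
    if p is None:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            try:
                p, err = _imhof_sf(t, coeffs)
            except Exception:
                p, err = np.nan, np.inf
        if not np.isfinite(p) or p < max(1e-9, 10 * err) or p > 1 + 1e-8:
            p = _ltz_sf(t, coeffs)
    return float(np.clip(p, P_FLOOR, 1.0))


def test_genes(
    X: ExpressionMatrix,
    model: SpacoModel,
    L: MoranOperator,
    alpha: float = 0.05,
    method: str = "bh",
) -> pd.DataFrame:
    """Per-gene spatial variability test.

    ``X`` is the scaled spots x genes matrix (the same centring/scaling
    convention used for fitting).  Returns a table with the statistic, raw
    one-sided p-value, multiplicity-adjusted p-value and a significance
    flag at ``alpha``; genes dropped during preprocessing appear as NA
    rows.  Sorted by increasing p-value, NA rows last.
    """
    if model.k is None:
        raise ValueError("model has no selected components; run select_components")
    if model.k == 0:
        raise ValueError(
            "no significant spatial components (k = 0); the gene test is undefined"
        )
    if X.layer != "scaled":
        raise ValueError(f"test_genes expects scaled data, got layer={X.layer!r}")
    if X.n_spots != L.n:
        raise ValueError("spot-count mismatch between matrix and operator")
    coeffs = null_coefficients(model, L)
    B = L.matvec(model.S_k)  # n x k
    proj = B.T @ X.X  # k x p
    t = (proj**2).sum(axis=0)
    pvals = tail_probabilities(t, coeffs)
    if method == "bh":
        adj = multipletests(pvals, method="fdr_bh")[1]
    elif method == "bonferroni":
        adj = multipletests(pvals, method="bonferroni")[1]
    else:
        raise ValueError(f"unknown multiple-testing method {method!r}")
    table = pd.DataFrame({
        "gene_id": X.gene_ids,
        "statistic": t,
        "p_value": pvals,
        "p_adjusted": adj,
        "significant": adj <= alpha,
    })
    if X.dropped_genes:
        na = pd.DataFrame({
            "gene_id": X.dropped_genes,
            "statistic": np.nan,
            "p_value": np.nan,
            "p_adjusted": np.nan,
            "significant": False,
        })
        table = pd.concat([table, na], ignore_index=True)
    return table.sort_values(
        "p_value", kind="stable", na_position="last"
    ).reset_index(drop=True)
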