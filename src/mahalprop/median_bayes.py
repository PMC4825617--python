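"""Median-style estimators of P and the quantile-ladder posterior mean.

* ``median_estimate`` -- ``1 - G(L_0.5 / n)``: the noncentrality whose
  median reproduces the observed statistic, pushed through the
  chi-square survival function.  Median-unbiased by construction but
  equal to 1 whenever ``F0`` falls below the central median.
* ``modified_median_estimate`` -- caps the median estimate by
  ``1 - G(M)`` where ``M`` is the posterior median of the index of a
  randomly drawn control (chi-square prior on nu1 df, noncentral-F
  likelihood), so the estimate stays credible as ``lambda0 -> 0``.
* ``posterior_mean_estimate`` -- averages ``1 - G(L_q / n)`` over a
  ladder of quantiles ``q = r/R``, the posterior mean implied by
  treating the exact confidence limits as credible limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    Dims,
    DomainError,
    Estimate,
    NumericalError,
    chi2_sf,
    compute_F0,
)
from .inversion import invert_noncentrality, invert_noncentrality_batch

__all__ = [
    "PosteriorGrid",
    "median_estimate",
    "modified_median_estimate",
    "posterior_mean_estimate",
    "posterior_median_lambda",
    "posterior_grid",
    "median_batch",
    "modified_median_batch",
    "posterior_mean_batch",
]

#: number of grid nodes for the posterior integration
_GRID_NODES = 2000


@dataclass(frozen=True)
class PosteriorGrid:
    """Discretised posterior of the random-control index lambda-tilde."""

    support: np.ndarray
    density: np.ndarray
    cumulative: np.ndarray

    @property
    def median(self) -> float:
        return float(np.interp(0.5, self.cumulative, self.support))


def _grid(F0: float, dims: Dims, nodes: int) -> np.ndarray:
    upper_L = invert_noncentrality(F0, 0.001, dims)
    q = stats.chi2.ppf(1.0 - 1e-6, dims.nu1) + 5.0 * upper_L / dims.n
    half = nodes // 2
    log_part = np.geomspace(q * 1e-8, q, half)
    lin_part = np.linspace(0.0, q, nodes - half + 1)
    return np.unique(np.concatenate([log_part, lin_part]))


def posterior_grid(F0: float, dims: Dims, nodes: int = _GRID_NODES) -> PosteriorGrid:
    """Normalised posterior of lambda-tilde given the observed ``F0``.

    Prior: chi-square on nu1 df.  Likelihood: noncentral F(nu1, nu2)
    density of ``F0`` at noncentrality ``n * lambda``.  At ``F0 = 0``
    the likelihood degenerates for nu1 > 2; its leading lambda-dependent
    factor ``exp(-n lambda / 2)`` is used instead.
    """
    if F0 < 0:
        raise DomainError(f"F0 must be nonnegative, got {F0}")
    grid = _grid(F0, dims, nodes)
    if F0 <= 0.0:
        like = np.exp(-dims.n * grid / 2.0)
    else:
        like = stats.ncf.pdf(F0, dims.nu1, dims.nu2, dims.n * grid)
    dens = stats.chi2.pdf(grid, dims.nu1) * like
    if not np.all(np.isfinite(dens)):
        raise NumericalError(f"non-finite posterior density at F0={F0}, dims={dims}")
    cum = np.concatenate([[0.0], np.cumsum(np.diff(grid) * (dens[1:] + dens[:-1]) / 2.0)])
    total = cum[-1]
    if total <= 0:
        raise NumericalError(f"posterior mass vanished at F0={F0}, dims={dims}")
    return PosteriorGrid(support=grid, density=dens / total, cumulative=cum / total)


def posterior_median_lambda(F0: float, dims: Dims, nodes: int = _GRID_NODES) -> float:
    """Posterior median of the random-control index lambda-tilde."""
    return posterior_grid(F0, dims, nodes).median


def median_estimate(lambda0: float, dims: Dims) -> Estimate:
    """Median estimator ``1 - G(L_0.5 / n)``."""
    F0 = compute_F0(lambda0, dims)
    L, truncated = invert_noncentrality(F0, 0.5, dims, full_output=True)
    return Estimate.of("median", float(chi2_sf(L / dims.n, dims.nu1)), truncated=truncated)


def modified_median_estimate(lambda0: float, dims: Dims) -> Estimate:
    """Median estimator capped by the posterior-median alternative."""
    pd = median_estimate(lambda0, dims)
    m = posterior_median_lambda(compute_F0(lambda0, dims), dims)
    alt = float(chi2_sf(m, dims.nu1))
    value = min(pd.value, alt)
    return Estimate.of("modified_median", value, posterior_median=m,
                       capped=alt < pd.value)


def _ladder(R: int, ladder: str) -> tuple[np.ndarray, int]:
    if R < 2:
        raise DomainError(f"R must be >= 2, got {R}")
    if ladder == "exclusive":
        # quantiles r/R for r = 1..R-1; the r = R term (quantile 1) is
        # undefined and the sum is averaged over the R-1 usable terms.
        return np.arange(1, R) / R, R - 1
    if ladder == "inclusive-truncated":
        # keep the divisor R; the quantile-1 limit truncates to L = 0,
        # contributing G(0) = 0 to the sum.
        return np.arange(1, R) / R, R
    raise DomainError(f"unknown ladder convention: {ladder!r}")


def posterior_mean_estimate(
    lambda0: float, dims: Dims, R: int = 500, ladder: str = "exclusive"
) -> Estimate:
    """Mean of ``1 - G(L_{r/R} / n)`` over the quantile ladder."""
    F0 = compute_F0(lambda0, dims)
    qs, divisor = _ladder(R, ladder)
    total = 0.0
    for q in qs:
        total += stats.chi2.cdf(invert_noncentrality(F0, q, dims) / dims.n, dims.nu1)
    return Estimate.of("posterior_mean", 1.0 - total / divisor, R=R, ladder=ladder)


# ---------------------------------------------------------------------------
# batch variants used by the simulation harness

def median_batch(F0, dims: Dims) -> np.ndarray:
    L = invert_noncentrality_batch(F0, 0.5, dims)
    return chi2_sf(L / dims.n, dims.nu1)


def modified_median_batch(F0, dims: Dims, nodes: int = _GRID_NODES) -> np.ndarray:
    F0 = np.asarray(F0, dtype=float)
    pd = median_batch(F0, dims)
    out = np.empty_like(pd)
    for i, f in enumerate(F0):
        m = posterior_median_lambda(float(f), dims, nodes)
        out[i] = min(pd[i], float(chi2_sf(m, dims.nu1)))
    return out


def posterior_mean_batch(F0, dims: Dims, R: int = 500, ladder: str = "exclusive") -> np.ndarray:
    F0 = np.asarray(F0, dtype=float)
    qs, divisor = _ladder(R, ladder)
    total = np.zeros_like(F0)
    for q in qs:
        L = invert_noncentrality_batch(F0, q, dims)
        total += stats.chi2.cdf(L / dims.n, dims.nu1)
    return 1.0 - total / divisor
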