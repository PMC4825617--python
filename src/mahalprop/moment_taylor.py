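"""Estimators of P built from point estimates of the noncentrality.

``lambda_bar`` is the minimum-variance unbiased estimator of the true
index lambda; it can be negative.  From it:

* ``moment_estimate`` -- truncates at zero, then applies the chi-square
  survival function.
* ``admissible_estimate`` -- uses the admissible shrinkage estimator
  ``nu1 (nu2 - 4) F0 / (n nu2)`` (requires nu2 > 4).
* ``taylor_estimate`` -- corrects ``lambda_bar`` with a second-order
  Taylor term driven by an unbiased estimate of its variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Dims, Estimate, UnsupportedConfigError, chi2_sf, compute_F0

__all__ = [
    "NoncentralityEstimates",
    "lambda_bar",
    "noncentrality_estimates",
    "moment_estimate",
    "admissible_estimate",
    "taylor_estimate",
    "var_coeffs_unbiased",
    "var_coeffs_true",
    "moment_batch",
    "admissible_batch",
    "taylor_batch",
]

#: below this value of lambda_bar the Taylor correction (which divides
#: by lambda_bar) falls back to the truncated moment estimator
_TAYLOR_EPS = 1e-8


@dataclass(frozen=True)
class NoncentralityEstimates:
    """The family of noncentrality point estimates for one observation."""

    lambda_bar: float
    lambda_hat: float
    lambda_tilde_adm: float | None
    lambda_star: float
    var_hat: float


def var_coeffs_unbiased(dims: Dims) -> tuple[float, float, float]:
    """(u0, u1, u2): Var-hat(lambda_bar) = u0 + u1*lb + u2*lb^2 is unbiased."""
    nu1, nu2, n = dims.nu1, dims.nu2, dims.n
    if nu2 <= 2:
        raise UnsupportedConfigError(f"variance coefficients require nu2 > 2, got {nu2}")
    return (
        2.0 * nu1 * (nu1 + nu2 - 2) / (n**2 * (nu2 - 2)),
        4.0 * (nu1 + nu2 - 2) / (n * (nu2 - 2)),
        2.0 / (nu2 - 2),
    )


def var_coeffs_true(dims: Dims) -> tuple[float, float, float]:
    """(v0, v1, v2): Var(lambda_bar) = v0 + v1*lam + v2*lam^2 (nu2 > 4)."""
    nu1, nu2, n = dims.nu1, dims.nu2, dims.n
    if nu2 <= 4:
        raise UnsupportedConfigError(f"Var(lambda_bar) requires nu2 > 4, got {nu2}")
    return (
        2.0 * nu1 * (nu1 + nu2 - 2) / (n**2 * (nu2 - 4)),
        4.0 * (nu1 + nu2 - 2) / (n * (nu2 - 4)),
        2.0 / (nu2 - 4),
    )


def _lambda_bar_batch(F0, dims: Dims) -> np.ndarray:
    nu1, nu2 = dims.nu1, dims.nu2
    return (nu1 * (nu2 - 2) * np.asarray(F0, dtype=float) / nu2 - nu1) / dims.n


def lambda_bar(F0: float, dims: Dims) -> float:
    """Unbiased estimator of lambda; may be negative.  Requires nu2 > 2."""
    if dims.nu2 <= 2:
        raise UnsupportedConfigError(f"lambda_bar requires nu2 > 2, got nu2={dims.nu2}")
    if F0 < 0:
        raise ValueError(f"F0 must be nonnegative, got {F0}")
    return float(_lambda_bar_batch(F0, dims))


def _lambda_star_batch(F0, dims: Dims) -> np.ndarray:
    nu1 = dims.nu1
    lb = _lambda_bar_batch(F0, dims)
    u0, u1, u2 = var_coeffs_unbiased(dims)
    var = u0 + u1 * lb + u2 * lb**2
    if nu1 == 2:
        # the (nu1/2 - 1)/lambda_bar term vanishes identically
        lstar = lb + var / 4.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            lstar = lb - var / 2.0 * ((nu1 / 2.0 - 1.0) / lb - 0.5)
    fallback = lb <= _TAYLOR_EPS
    return np.where(fallback, np.maximum(lb, 0.0), np.maximum(lstar, 0.0))


def noncentrality_estimates(F0: float, dims: Dims) -> NoncentralityEstimates:
    """All noncentrality point estimates derived from one observation."""
    lb = lambda_bar(F0, dims)
    u0, u1, u2 = var_coeffs_unbiased(dims)
    adm = None
    if dims.nu2 > 4:
        adm = dims.nu1 * (dims.nu2 - 4) * F0 / (dims.n * dims.nu2)
    return NoncentralityEstimates(
        lambda_bar=lb,
        lambda_hat=max(lb, 0.0),
        lambda_tilde_adm=adm,
        lambda_star=float(_lambda_star_batch(F0, dims)),
        var_hat=u0 + u1 * lb + u2 * lb**2,
    )


def moment_batch(F0, dims: Dims) -> np.ndarray:
    if dims.nu2 <= 2:
        raise UnsupportedConfigError(f"moment estimator requires nu2 > 2, got {dims.nu2}")
    return chi2_sf(np.maximum(_lambda_bar_batch(F0, dims), 0.0), dims.nu1)


def admissible_batch(F0, dims: Dims) -> np.ndarray:
    nu1, nu2 = dims.nu1, dims.nu2
    if nu2 <= 4:
        raise UnsupportedConfigError(f"admissible estimator requires nu2 > 4, got {nu2}")
    lam = nu1 * (nu2 - 4) * np.asarray(F0, dtype=float) / (dims.n * nu2)
    return chi2_sf(lam, nu1)


def taylor_batch(F0, dims: Dims) -> np.ndarray:
    if dims.nu2 <= 4:
        raise UnsupportedConfigError(f"taylor estimator requires nu2 > 4, got {dims.nu2}")
    return chi2_sf(_lambda_star_batch(F0, dims), dims.nu1)


def moment_estimate(lambda0: float, dims: Dims) -> Estimate:
    """Truncated-unbiased-noncentrality estimator of P."""
    F0 = compute_F0(lambda0, dims)
    lb = lambda_bar(F0, dims)
    return Estimate.of("moment", float(moment_batch(F0, dims)),
                       lambda_bar=lb, truncated=lb < 0)


def admissible_estimate(lambda0: float, dims: Dims) -> Estimate:
    """Admissible-noncentrality estimator of P (nu2 > 4)."""
    F0 = compute_F0(lambda0, dims)
    return Estimate.of("admissible", float(admissible_batch(F0, dims)))


def taylor_estimate(lambda0: float, dims: Dims) -> Estimate:
    """Second-order Taylor-corrected estimator of P (nu2 > 4)."""
    F0 = compute_F0(lambda0, dims)
    lb = lambda_bar(F0, dims)
    return Estimate.of("taylor", float(taylor_batch(F0, dims)),
                       lambda_bar=lb, fallback=lb <= _TAYLOR_EPS)
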