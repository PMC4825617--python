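"""Plug-in maximum likelihood estimators of the proportion P.

Both estimators replace unknown population parameters by their sample
estimates inside the defining probability:

* ``f_tail`` -- the upper tail of a central F(nu1, nu2) distribution at
  the scaled one-sample Hotelling statistic; the p-value of the test
  that the case belongs to the control population.
* ``chi2_tail`` -- the upper tail of a chi-square(nu1) distribution at
  the maximum-likelihood rescaling ``n * lambda0 / (n - 1)``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import Dims, DomainError, Estimate, chi2_sf

__all__ = ["f_tail", "chi2_tail", "f_tail_batch", "chi2_tail_batch", "hotelling_t2"]


def hotelling_t2(lambda0: float, dims: Dims) -> float:
    """One-sample Hotelling statistic ``T^2 = n * lambda0 / (n + 1)``."""
    return dims.n * lambda0 / (dims.n + 1)


def f_tail_batch(lambda0, dims: Dims) -> np.ndarray:
    # multiplier assembled in one expression: n*nu2 / ((n+1)(n-1)nu1)
    n = dims.n
    x = n * dims.nu2 * np.asarray(lambda0, dtype=float) / ((n + 1) * (n - 1) * dims.nu1)
    return stats.f.sf(x, dims.nu1, dims.nu2)


def chi2_tail_batch(lambda0, dims: Dims) -> np.ndarray:
    n = dims.n
    return chi2_sf(n * np.asarray(lambda0, dtype=float) / (n - 1), dims.nu1)


def _check(lambda0: float) -> None:
    if lambda0 < 0:
        raise DomainError(f"lambda0 must be nonnegative, got {lambda0}")


def f_tail(lambda0: float, dims: Dims) -> Estimate:
    """Central-F tail (Hotelling p-value) plug-in estimator."""
    _check(lambda0)
    value = float(f_tail_batch(lambda0, dims))
    return Estimate.of("f_tail", value, t2=hotelling_t2(lambda0, dims))


def chi2_tail(lambda0: float, dims: Dims) -> Estimate:
    """Chi-square tail plug-in estimator."""
    _check(lambda0)
    return Estimate.of("chi2_tail", float(chi2_tail_batch(lambda0, dims)))
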