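"""Computing the sample Mahalanobis index from raw control data."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Dims, DomainError, NumericalError

__all__ = ["compute_lambda0_from_data", "read_matrix"]

#: condition number of S above which the quadratic form is refused
_COND_LIMIT = 1e12


def compute_lambda0_from_data(controls, case_profile) -> tuple[float, Dims]:
    """Sample Mahalanobis index of a case against a control sample.

    ``controls`` is an (n, nu1) matrix of control scores;
    ``case_profile`` a length-nu1 vector.  The covariance uses divisor
    n - 1.  Returns ``(lambda0, Dims(nu1, n - nu1))``.
    """
    x = np.asarray(controls, dtype=float)
    xstar = np.asarray(case_profile, dtype=float).ravel()
    if x.ndim != 2:
        raise DomainError(f"controls must be a 2-D matrix, got shape {x.shape}")
    n, nu1 = x.shape
    if xstar.shape != (nu1,):
        raise DomainError(
            f"case profile has {xstar.size} scores but controls have {nu1} columns"
        )
    if n <= nu1 + 1:
        raise DomainError(
            f"need n > nu1 + 1 controls (nu2 >= 1 and nonsingular S); got n={n}, nu1={nu1}"
        )
    xbar = x.mean(axis=0)
    S = np.cov(x, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise NumericalError(
            f"sample covariance is singular or ill-conditioned (cond={cond:.3e}); "
            "check for collinear or constant score columns"
        )
    diff = xstar - xbar
    lam0 = float(diff @ np.linalg.solve(S, diff))
    return max(lam0, 0.0), Dims(nu1, n - nu1)


def read_matrix(path: str) -> np.ndarray:
    """Read a CSV/TSV numeric matrix; a non-numeric first row is a header."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    try:
        df = pd.read_csv(path, sep=sep, header=None)
        return df.to_numpy(dtype=float)
    except ValueError:
        df = pd.read_csv(path, sep=sep)
        return df.to_numpy(dtype=float)
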