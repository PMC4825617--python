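"""Core domain types and the exact sampling law of the case statistic.

A case's profile of ``nu1`` scores is compared against a normative
(control) sample of size ``n`` via the sample Mahalanobis index
``lambda0``.  The rescaled statistic

    F0 = n * nu2 * lambda0 / ((n - 1) * nu1),      nu2 = n - nu1,

follows a noncentral F distribution with ``(nu1, nu2)`` degrees of
freedom and noncentrality ``n * lambda``, where ``lambda`` is the case's
true (population) Mahalanobis index.  Everything else in this package is
built on that law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from scipy import stats

__all__ = [
    "Dims",
    "CaseIndex",
    "IntervalEstimate",
    "Estimate",
    "DomainError",
    "UnsupportedConfigError",
    "NumericalError",
    "compute_F0",
    "lambda0_from_F0",
    "chi2_cdf",
    "chi2_sf",
    "chi2_pdf",
]


class DomainError(ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class UnsupportedConfigError(ValueError):
    """The degrees of freedom do not support the requested estimator."""


class NumericalError(RuntimeError):
    """A numerical routine failed to converge or produced non-finite values."""


@dataclass(frozen=True)
class Dims:
    """Degrees of freedom of the problem.

    Attributes
    ----------
    nu1 : int
        Number of scores per profile (numerator degrees of freedom).
    nu2 : int
        Residual degrees of freedom, ``n - nu1``.
    """

    nu1: int
    nu2: int

    def __post_init__(self) -> None:
        if int(self.nu1) != self.nu1 or int(self.nu2) != self.nu2:
            raise DomainError("nu1 and nu2 must be integers")
        if self.nu1 < 1 or self.nu2 < 1:
            raise DomainError(f"nu1 and nu2 must be >= 1, got ({self.nu1}, {self.nu2})")
        object.__setattr__(self, "nu1", int(self.nu1))
        object.__setattr__(self, "nu2", int(self.nu2))

    @property
    def n(self) -> int:
        """Control-sample size, ``nu1 + nu2``."""
        return self.nu1 + self.nu2

    @classmethod
    def from_n(cls, nu1: int, n: int) -> "Dims":
        return cls(nu1, n - nu1)


@dataclass(frozen=True)
class CaseIndex:
    """A case's observed sample Mahalanobis index and its rescaling."""

    lambda0: float
    F0: float

    @classmethod
    def from_lambda0(cls, lambda0: float, dims: Dims) -> "CaseIndex":
        return cls(float(lambda0), compute_F0(lambda0, dims))


@dataclass(frozen=True)
class IntervalEstimate:
    """A two-sided confidence interval for the proportion P."""

    level: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise NumericalError(
                f"invalid interval [{self.lower}, {self.upper}] at level {self.level}"
            )

    def contains(self, p: float) -> bool:
        return self.lower <= p <= self.upper


@dataclass(frozen=True)
class Estimate:
    """One named estimator's value for the proportion P.

    ``value`` is intended as a probability but the polynomial estimators
    may leave [0, 1]; ``in_range`` records whether it did.
    """

    method: str
    value: float
    in_range: bool = field(default=True)
    notes: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def of(cls, method: str, value: float, **notes: Any) -> "Estimate":
        return cls(method=method, value=float(value),
                   in_range=bool(0.0 <= value <= 1.0), notes=notes)


def compute_F0(lambda0: float, dims: Dims) -> float:
    """Rescale a sample Mahalanobis index to its F-distributed form.

    Returns ``n * nu2 * lambda0 / ((n - 1) * nu1)``.
    """
    if lambda0 < 0:
        raise DomainError(f"lambda0 must be nonnegative, got {lambda0}")
    n = dims.n
    return n * dims.nu2 * float(lambda0) / ((n - 1) * dims.nu1)


def lambda0_from_F0(F0, dims: Dims):
    """Inverse of :func:`compute_F0`; accepts scalars or arrays."""
    n = dims.n
    return (n - 1) * dims.nu1 * F0 / (n * dims.nu2)


def chi2_cdf(x, nu1: int):
    """CDF of the chi-square distribution on ``nu1`` degrees of freedom."""
    return stats.chi2.cdf(x, nu1)


def chi2_sf(x, nu1: int):
    """Survival function of the chi-square distribution on ``nu1`` df."""
    return stats.chi2.sf(x, nu1)


def chi2_pdf(x, nu1: int):
    return stats.chi2.pdf(x, nu1)
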