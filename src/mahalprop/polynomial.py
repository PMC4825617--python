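"""Moment-matched polynomial estimators of P.

The proportion ``P = Pr(chi2_nu1 > lambda)`` is approximated on a data-
driven interval ``[a, b]`` by a degree-r polynomial ``sum a_i lambda^i``
using one of two constructions:

* ``bernstein`` -- the Bernstein operator applied to the chi-square CDF;
* ``quadrature`` -- the chi-square *density* is interpolated at r
  equally spaced nodes (a Newton-Cotes-style rule, written in the
  binomial-coefficient form C(sx, i) C(s(1-x), s-i) which is exactly the
  Lagrange basis at nodes i/s) and integrated in closed form.

Because every raw moment E(F0^i) is itself a polynomial of degree i in
lambda, coefficients ``b_i`` with ``sum b_i E(F0^i) = sum a_i lambda^i``
can be found by a triangular solve, making ``sum b_i F0^i``
approximately unbiased for P.  The i-th moment exists only for
``nu2 > 2i``, which caps the usable degree at ``r < nu2 / 2``.

Moment polynomials are computed in exact rational arithmetic (cumulants
of the noncentral chi-square, converted to raw moments) and cached per
configuration; endpoints and coefficients are recomputed per observed
statistic, since they depend on quantile inversions at the sample value.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb, factorial

import numpy as np
from scipy import stats

from .core import (
    Dims,
    DomainError,
    Estimate,
    NumericalError,
    UnsupportedConfigError,
    chi2_cdf,
    chi2_pdf,
    compute_F0,
)
from .inversion import invert_noncentrality_batch

__all__ = [
    "MomentPoly",
    "Endpoints",
    "PolynomialApprox",
    "ncx2_moment_poly",
    "f0_moment_poly",
    "max_degree",
    "select_endpoints",
    "select_endpoints_batch",
    "bernstein_target_coeffs",
    "quadrature_target_coeffs",
    "solve_matched_coeffs",
    "build_approx",
    "polynomial_estimate",
    "polynomial_batch",
    "FAMILIES",
    "DEGREES",
]

FAMILIES = ("bernstein", "quadrature")
DEGREES = (4, 7, 10)

#: relative residual above which the triangular solve warns
_RESIDUAL_WARN = 1e-6


@dataclass(frozen=True)
class MomentPoly:
    """Coefficients of lambda^0..lambda^i in E(F0^i)."""

    order: int
    coeffs: tuple[float, ...]


@dataclass(frozen=True)
class Endpoints:
    a: float
    b: float
    fallback: bool = False


@dataclass(frozen=True)
class PolynomialApprox:
    """One fitted polynomial estimator: target and matched coefficients."""

    family: str
    degree: int
    a: float
    b: float
    target_coeffs: tuple[float, ...]
    matched_coeffs: tuple[float, ...]


@lru_cache(maxsize=None)
def ncx2_moment_poly(i: int, nu: int) -> tuple[Fraction, ...]:
    """Exact coefficients of delta^0..delta^i in E[(chi2_nu(delta))^i].

    Route: cumulants kappa_j = 2^(j-1) (j-1)! (nu + j delta), converted
    to raw moments by mu_m = sum_{j<m} C(m-1, j) kappa_{m-j} mu_j.
    """
    if i < 0:
        raise DomainError(f"moment order must be >= 0, got {i}")
    kap = {
        j: (Fraction(2) ** (j - 1) * factorial(j - 1) * nu,
            Fraction(2) ** (j - 1) * factorial(j - 1) * j)
        for j in range(1, i + 1)
    }
    moments: list[list[Fraction]] = [[Fraction(1)]]
    for m in range(1, i + 1):
        acc = [Fraction(0)] * (m + 1)
        for j in range(m):
            c = comb(m - 1, j)
            for p, kc in enumerate(kap[m - j]):
                for q, mc in enumerate(moments[j]):
                    acc[p + q] += c * kc * mc
        moments.append(acc)
    return tuple(moments[i])


@lru_cache(maxsize=None)
def _f0_moment_fractions(i: int, nu1: int, nu2: int, n: int) -> tuple[Fraction, ...]:
    base = ncx2_moment_poly(i, nu1)
    denom = Fraction(1)
    for k in range(1, i + 1):
        denom *= Fraction(nu2, 2) - k
    scale = Fraction(nu2) ** i / (Fraction(2 * nu1) ** i * denom)
    return tuple(base[k] * Fraction(n) ** k * scale for k in range(i + 1))


def f0_moment_poly(i: int, dims: Dims) -> MomentPoly:
    """Coefficients of lambda^0..lambda^i in E(F0^i); needs nu2 > 2i."""
    if i < 0:
        raise DomainError(f"moment order must be >= 0, got {i}")
    if dims.nu2 <= 2 * i:
        raise UnsupportedConfigError(
            f"E(F0^{i}) does not exist for nu2={dims.nu2} (requires nu2 > {2 * i}; "
            f"equivalently degree < (n - nu1)/2)"
        )
    fr = _f0_moment_fractions(i, dims.nu1, dims.nu2, dims.n)
    return MomentPoly(order=i, coeffs=tuple(float(c) for c in fr))


def max_degree(dims: Dims) -> int:
    """Largest usable polynomial degree: the last r with nu2 > 2r."""
    return (dims.nu2 - 1) // 2


# ---------------------------------------------------------------------------
# endpoint selection

def select_endpoints_batch(F0, dims: Dims) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised endpoint rule; returns (a, b, fallback_mask)."""
    F0 = np.asarray(F0, dtype=float)
    n = dims.n
    b = invert_noncentrality_batch(F0, 0.001, dims) / n
    med = invert_noncentrality_batch(F0, 0.5, dims) / n
    a_hi = invert_noncentrality_batch(F0, 0.999, dims) / n
    mode = max(dims.nu1 - 2, 0)
    a = np.where(med > mode, 0.99 * med, a_hi)
    bad = b <= a
    a = np.where(bad, 0.0, a)
    b = np.where(bad, stats.chi2.ppf(0.999, dims.nu1), b)
    return a, b, bad


def select_endpoints(F0: float, dims: Dims) -> Endpoints:
    """Approximation interval for one observed statistic.

    ``b`` is the upper 0.001 confidence limit of lambda.  ``a`` is just
    below the median limit when that limit exceeds the chi-square mode,
    otherwise the lower 0.999 limit.  A degenerate bracket (everything
    truncated to 0) falls back to [0, chi-square 0.999-quantile].
    """
    if F0 < 0:
        raise DomainError(f"F0 must be nonnegative, got {F0}")
    a, b, bad = select_endpoints_batch(np.array([F0]), dims)
    return Endpoints(a=float(a[0]), b=float(b[0]), fallback=bool(bad[0]))


# ---------------------------------------------------------------------------
# target coefficient construction (vectorised over endpoint arrays)

@lru_cache(maxsize=None)
def _bernstein_basis_matrix(r: int) -> np.ndarray:
    """Row i: coefficients in x of C(r,i) x^i (1-x)^(r-i); exact ints."""
    mat = np.zeros((r + 1, r + 1))
    for i in range(r + 1):
        for m in range(r - i + 1):
            mat[i, i + m] = comb(r, i) * comb(r - i, m) * (-1) ** m
    return mat


@lru_cache(maxsize=None)
def _lagrange_basis_matrix(s: int) -> np.ndarray:
    """Row i: coefficients in x of the Lagrange basis at nodes j/s.

    Computed as the exact rational inverse of the Vandermonde matrix at
    the nodes, so the interpolation identity holds to rounding only.
    """
    if s == 0:
        return np.array([[1.0]])
    m = s + 1
    aug = [
        [Fraction(i, s) ** j for j in range(m)] + [Fraction(int(i == k)) for k in range(m)]
        for i in range(m)
    ]
    for c in range(m):
        p = next(r for r in range(c, m) if aug[r][c] != 0)
        aug[c], aug[p] = aug[p], aug[c]
        inv = 1 / aug[c][c]
        aug[c] = [v * inv for v in aug[c]]
        for r_ in range(m):
            if r_ != c and aug[r_][c] != 0:
                f = aug[r_][c]
                aug[r_] = [v - f * w for v, w in zip(aug[r_], aug[c])]
    vinv = np.array([[float(aug[r_][m + c]) for c in range(m)] for r_ in range(m)])
    # values @ basis gives x-coefficients:  coeffs = V^{-1} values
    return vinv.T


def _x_poly_to_lambda(coeffs_x: np.ndarray, a: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Expand sum_m c_m ((lambda - a)/w)^m into powers of lambda."""
    npts, deg1 = coeffs_x.shape
    out = np.zeros_like(coeffs_x)
    for m_ in range(deg1):
        cm = coeffs_x[:, m_] / w**m_
        for k in range(m_ + 1):
            out[:, k] += cm * comb(m_, k) * (-a) ** (m_ - k)
    return out


def _bernstein_targets_batch(a: np.ndarray, b: np.ndarray, r: int, nu1: int) -> np.ndarray:
    w = b - a
    nodes = a[:, None] + w[:, None] * np.arange(r + 1) / r
    gvals = chi2_cdf(nodes, nu1)
    coeffs_x = gvals @ _bernstein_basis_matrix(r)
    out = -_x_poly_to_lambda(coeffs_x, a, w)
    out[:, 0] += 1.0
    return out


def _quadrature_targets_batch(a: np.ndarray, b: np.ndarray, r: int, nu1: int) -> np.ndarray:
    w = b - a
    s = r - 1
    nodes = a[:, None] + w[:, None] * (np.arange(s + 1) / s if s else np.array([0.0]))
    vals = chi2_pdf(nodes, nu1) * w[:, None]
    coeffs_x = vals @ _lagrange_basis_matrix(s)
    integ = np.zeros((a.shape[0], r + 1))
    integ[:, 1:] = coeffs_x / (np.arange(s + 1) + 1.0)
    out = -_x_poly_to_lambda(integ, a, w)
    out[:, 0] += 1.0 - chi2_cdf(a, nu1)
    return out


def bernstein_target_coeffs(a: float, b: float, r: int, nu1: int) -> np.ndarray:
    """Coefficients of lambda^0..r of the Bernstein CDF approximation.

    The polynomial reproduces ``1 - G`` exactly at lambda = a and b.
    """
    if not a < b:
        raise DomainError(f"need a < b, got ({a}, {b})")
    if r < 1:
        raise DomainError(f"degree must be >= 1, got {r}")
    return _bernstein_targets_batch(np.array([a]), np.array([b]), r, nu1)[0]


def quadrature_target_coeffs(a: float, b: float, r: int, nu1: int) -> np.ndarray:
    """Coefficients of lambda^0..r of the quadrature CDF approximation."""
    if not a < b:
        raise DomainError(f"need a < b, got ({a}, {b})")
    if r < 2:
        raise DomainError(f"quadrature degree must be >= 2, got {r}")
    return _quadrature_targets_batch(np.array([a]), np.array([b]), r, nu1)[0]


# ---------------------------------------------------------------------------
# matching

def _moment_matrix(r: int, dims: Dims) -> list[tuple[float, ...]]:
    return [f0_moment_poly(i, dims).coeffs for i in range(r + 1)]


def _solve_batch(targets: np.ndarray, moments: list[tuple[float, ...]]) -> np.ndarray:
    r = targets.shape[1] - 1
    out = np.zeros_like(targets)
    for j in range(r, -1, -1):
        acc = targets[:, j].copy()
        for i in range(j + 1, r + 1):
            acc -= out[:, i] * moments[i][j]
        out[:, j] = acc / moments[j][j]
    return out


def _roundtrip_residual(bcoef: np.ndarray, targets: np.ndarray,
                        moments: list[tuple[float, ...]]) -> np.ndarray:
    recon = np.zeros_like(targets)
    for i, mom in enumerate(moments):
        for j, c in enumerate(mom):
            recon[:, j] += bcoef[:, i] * c
    # relative to the dominant coefficient: entries near 0 carry rounding
    # noise that is meaningless against their own magnitude
    scale = np.max(np.abs(targets), axis=1, keepdims=True)
    return np.max(np.abs(recon - targets) / np.maximum(scale, 1e-300), axis=1)


def solve_matched_coeffs(target_coeffs, moments: list[MomentPoly]) -> np.ndarray:
    """Solve sum_i b_i E(F0^i) = sum_j a_j lambda^j for the b_i.

    The system is triangular (E(F0^i) has exact degree i) and is solved
    by back-substitution; the coefficient identity is re-checked and a
    ``NumericalError`` raised if the relative residual exceeds 1e-6.
    """
    target = np.asarray(target_coeffs, dtype=float)
    r = target.shape[0] - 1
    if len(moments) != r + 1:
        raise DomainError("need one moment polynomial per coefficient 0..r")
    mom = [m.coeffs if isinstance(m, MomentPoly) else tuple(m) for m in moments]
    bcoef = _solve_batch(target[None, :], mom)
    resid = float(_roundtrip_residual(bcoef, target[None, :], mom)[0])
    if resid > _RESIDUAL_WARN:
        raise NumericalError(f"coefficient match residual {resid:.2e} exceeds {_RESIDUAL_WARN}")
    return bcoef[0]


def build_approx(F0: float, dims: Dims, degree: int, family: str) -> PolynomialApprox:
    """Fit one polynomial estimator for the observed statistic."""
    if family not in FAMILIES:
        raise DomainError(f"family must be one of {FAMILIES}, got {family!r}")
    if dims.nu2 <= 2 * degree:
        raise UnsupportedConfigError(
            f"degree {degree} needs nu2 > {2 * degree} (r < (n - nu1)/2); got nu2={dims.nu2}"
        )
    ep = select_endpoints(F0, dims)
    if family == "bernstein":
        target = bernstein_target_coeffs(ep.a, ep.b, degree, dims.nu1)
    else:
        target = quadrature_target_coeffs(ep.a, ep.b, degree, dims.nu1)
    moments = [f0_moment_poly(i, dims) for i in range(degree + 1)]
    matched = solve_matched_coeffs(target, moments)
    return PolynomialApprox(
        family=family, degree=degree, a=ep.a, b=ep.b,
        target_coeffs=tuple(target), matched_coeffs=tuple(matched),
    )


def _horner(coeffs: np.ndarray, x: np.ndarray) -> np.ndarray:
    val = coeffs[:, -1].copy() if coeffs.ndim == 2 else np.full_like(x, coeffs[-1])
    r = coeffs.shape[-1] - 1
    for j in range(r - 1, -1, -1):
        val = val * x + (coeffs[:, j] if coeffs.ndim == 2 else coeffs[j])
    return val


def polynomial_batch(F0, dims: Dims, degree: int, family: str,
                     clip: bool = False) -> np.ndarray:
    """Vectorised polynomial estimator over an array of F0 values."""
    if family not in FAMILIES:
        raise DomainError(f"family must be one of {FAMILIES}, got {family!r}")
    if dims.nu2 <= 2 * degree:
        raise UnsupportedConfigError(
            f"degree {degree} needs nu2 > {2 * degree} (r < (n - nu1)/2); got nu2={dims.nu2}"
        )
    F0 = np.asarray(F0, dtype=float)
    mom = [f0_moment_poly(i, dims).coeffs for i in range(degree + 1)]
    a, b, _ = select_endpoints_batch(F0, dims)
    if family == "bernstein":
        targets = _bernstein_targets_batch(a, b, degree, dims.nu1)
    else:
        targets = _quadrature_targets_batch(a, b, degree, dims.nu1)
    bcoef = _solve_batch(targets, mom)
    vals = _horner(bcoef, F0)
    if clip:
        vals = np.clip(vals, 0.0, 1.0)
    return vals


def polynomial_estimate(lambda0: float, dims: Dims, degree: int, family: str,
                        clip: bool = False) -> Estimate:
    """Moment-matched polynomial estimator of P for one case."""
    F0 = compute_F0(lambda0, dims)
    approx = build_approx(F0, dims, degree, family)
    raw = float(_horner(np.asarray(approx.matched_coeffs), np.asarray(F0)))
    value = min(max(raw, 0.0), 1.0) if clip else raw
    name = f"{family}{degree}"
    return Estimate.of(name, value, raw_value=raw, clipped=clip and raw != value,
                       a=approx.a, b=approx.b)
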