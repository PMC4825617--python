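"""Estimation of the abnormality of a case's Mahalanobis index.

Given a case profile and a normative control sample, this package
estimates P, the proportion of the normative population whose (squared)
Mahalanobis distance from the population mean exceeds the case's, with
fourteen point estimators, exact confidence intervals, and a Monte-Carlo
harness for comparing the estimators' bias, RMSE, median error and
average absolute error.
"""

from .core import (
    CaseIndex,
    Dims,
    DomainError,
    Estimate,
    IntervalEstimate,
    NumericalError,
    UnsupportedConfigError,
    compute_F0,
    lambda0_from_F0,
)
from .data import compute_lambda0_from_data
from .inversion import confidence_interval, invert_noncentrality
from .median_bayes import (
    median_estimate,
    modified_median_estimate,
    posterior_mean_estimate,
    posterior_median_lambda,
)
from .moment_taylor import (
    admissible_estimate,
    lambda_bar,
    moment_estimate,
    taylor_estimate,
)
from .plugin import chi2_tail, f_tail
from .polynomial import polynomial_estimate
from .simulation import (
    ESTIMATOR_NAMES,
    PopulationSpec,
    SimConfig,
    estimator_profile,
    make_case_profile,
    run_study,
    true_lambda_from_P,
)

__version__ = "0.1.0"

_SCALAR_ESTIMATORS = {
    "f_tail": f_tail,
    "chi2_tail": chi2_tail,
    "median": median_estimate,
    "modified_median": modified_median_estimate,
    "posterior_mean": posterior_mean_estimate,
    "moment": moment_estimate,
    "admissible": admissible_estimate,
    "taylor": taylor_estimate,
}


def estimate(method: str, lambda0: float, dims: Dims, clip: bool = False) -> Estimate:
    """Evaluate one named estimator of P for a single case."""
    if method in _SCALAR_ESTIMATORS:
        return _SCALAR_ESTIMATORS[method](lambda0, dims)
    for family in ("bernstein", "quadrature"):
        if method.startswith(family):
            return polynomial_estimate(lambda0, dims, int(method[len(family):]),
                                       family, clip=clip)
    raise DomainError(f"unknown estimator {method!r}; valid names: {ESTIMATOR_NAMES}")


__all__ = [
    "CaseIndex",
    "Dims",
    "DomainError",
    "Estimate",
    "IntervalEstimate",
    "NumericalError",
    "UnsupportedConfigError",
    "ESTIMATOR_NAMES",
    "PopulationSpec",
    "SimConfig",
    "estimate",
    "compute_F0",
    "lambda0_from_F0",
    "compute_lambda0_from_data",
    "confidence_interval",
    "invert_noncentrality",
    "median_estimate",
    "modified_median_estimate",
    "posterior_mean_estimate",
    "posterior_median_lambda",
    "moment_estimate",
    "admissible_estimate",
    "taylor_estimate",
    "lambda_bar",
    "chi2_tail",
    "f_tail",
    "polynomial_estimate",
    "estimator_profile",
    "make_case_profile",
    "run_study",
    "true_lambda_from_P",
]
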