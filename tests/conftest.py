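import numpy as np
import pytest

from mahalprop.core import Dims


@pytest.fixture
def rng():
    return np.random.default_rng(20160714)


@pytest.fixture
def dims_4_20():
    return Dims(4, 20)


@pytest.fixture
def dims_2_10():
    return Dims(2, 10)


def chi2_cdf_closed(x, nu1):
    """Closed-form chi-square CDF for nu1 in {2, 4}; independent oracle."""
    if nu1 == 2:
        return 1.0 - np.exp(-x / 2.0)
    if nu1 == 4:
        return 1.0 - np.exp(-x / 2.0) * (1.0 + x / 2.0)
    raise ValueError(nu1)


def draw_F0(rng, lam, dims, size):
    """Noncentral-F draws of the case statistic, independent of the package."""
    n = dims.n
    num = rng.noncentral_chisquare(dims.nu1, n * lam, size)
    den = rng.chisquare(dims.nu2, size)
    return (num / dims.nu1) / (den / dims.nu2)
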