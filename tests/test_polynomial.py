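from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mahalprop.core import Dims, DomainError, UnsupportedConfigError, compute_F0
from mahalprop.polynomial import (
    bernstein_target_coeffs,
    build_approx,
    f0_moment_poly,
    max_degree,
    ncx2_moment_poly,
    polynomial_batch,
    polynomial_estimate,
    quadrature_target_coeffs,
    select_endpoints,
    select_endpoints_batch,
    solve_matched_coeffs,
)

from conftest import draw_F0


def _sympy_ncx2_moment(i, nu, delta):
    """Independent oracle: i-th raw moment from the mgf, via sympy."""
    import sympy as sp

    t = sp.Symbol("t")
    mgf = (1 - 2 * t) ** sp.Rational(-nu, 2) * sp.exp(delta * t / (1 - 2 * t))
    return sp.nsimplify(sp.diff(mgf, t, i).subs(t, 0), rational=True)


class TestNcx2Moments:
    def test_zeroth_and_first(self):
        assert ncx2_moment_poly(0, 5) == (Fraction(1),)
        assert ncx2_moment_poly(1, 5) == (Fraction(5), Fraction(1))

    def test_second(self):
        nu = 3
        # (nu + d)^2 + 2(nu + 2d) = nu^2+2nu + (2nu+4)d + d^2
        assert ncx2_moment_poly(2, nu) == (
            Fraction(nu**2 + 2 * nu), Fraction(2 * nu + 4), Fraction(1)
        )

    @pytest.mark.parametrize("i", [3, 4, 5, 6])
    @pytest.mark.parametrize("nu", [2, 4, 7])
    def test_against_mgf_oracle(self, i, nu):
        import sympy as sp

        coeffs = ncx2_moment_poly(i, nu)
        d = sp.Symbol("delta")
        mine = sum(sp.Rational(c.numerator, c.denominator) * d**k for k, c in enumerate(coeffs))
        oracle = sp.expand(_sympy_ncx2_moment(i, nu, d))
        assert sp.simplify(mine - oracle) == 0

    def test_monte_carlo_cross_check(self, rng):
        nu, delta, i = 4, 3.0, 2
        coeffs = ncx2_moment_poly(i, nu)
        expected = sum(float(c) * delta**k for k, c in enumerate(coeffs))
        draws = rng.noncentral_chisquare(nu, delta, 200_000) ** i
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(expected, abs=3 * se)


class TestF0Moments:
    def test_first_moment_closed_form(self):
        # E(F0) = (nu1 + n lam) nu2 / (nu1 (nu2 - 2)); unbiasedness follows
        d = Dims(4, 20)
        mp = f0_moment_poly(1, d)
        assert mp.coeffs[0] == pytest.approx(d.nu2 / (d.nu2 - 2), rel=1e-14)
        assert mp.coeffs[1] == pytest.approx(d.n * d.nu2 / (d.nu1 * (d.nu2 - 2)), rel=1e-14)

    def test_second_moment_monte_carlo(self, rng):
        d = Dims(4, 20)
        lam = 1.0
        mp = f0_moment_poly(2, d)
        expected = mp.coeffs[0] + mp.coeffs[1] * lam + mp.coeffs[2] * lam**2
        draws = draw_F0(rng, lam, d, 1_000_000) ** 2
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(expected, abs=3 * se)

    def test_nonexistence_error(self):
        with pytest.raises(UnsupportedConfigError):
            f0_moment_poly(5, Dims(4, 10))
        f0_moment_poly(4, Dims(4, 10))  # boundary: exists for nu2 > 2i

    def test_leading_coefficient_positive(self):
        d = Dims(2, 22)
        for i in range(11):
            mp = f0_moment_poly(i, d)
            assert mp.coeffs[-1] > 0

    def test_max_degree(self):
        assert max_degree(Dims(2, 10)) == 4
        assert max_degree(Dims(4, 20)) == 9
        assert max_degree(Dims(8, 21)) == 10


class TestEndpoints:
    def test_nu1_2_mode_zero_rule(self):
        # mode is 0, so any positive median limit triggers the 0.99 rule
        d = Dims(2, 20)
        f0 = 5.0
        from mahalprop.inversion import invert_noncentrality

        ep = select_endpoints(f0, d)
        assert ep.a == pytest.approx(0.99 * invert_noncentrality(f0, 0.5, d) / d.n, rel=1e-9)

    def test_degenerate_fallback(self):
        d = Dims(4, 20)
        ep = select_endpoints(0.0, d)
        assert ep.fallback
        assert ep.a == 0.0
        assert ep.b == pytest.approx(stats.chi2.ppf(0.999, 4), rel=1e-12)

    @given(
        f0=st.floats(0.0, 60.0),
        nu1=st.sampled_from([2, 4, 8]),
        nu2=st.sampled_from([10, 20, 80]),
    )
    @settings(max_examples=200, deadline=None)
    def test_a_strictly_below_b(self, f0, nu1, nu2):
        a, b, _ = select_endpoints_batch(np.array([f0]), Dims(nu1, nu2))
        assert a[0] < b[0]


class TestBernsteinTargets:
    def test_degree_one_is_linear_interpolation(self):
        a, b, nu1 = 1.0, 9.0, 4
        coeffs = bernstein_target_coeffs(a, b, 1, nu1)
        Ga, Gb = stats.chi2.cdf([a, b], nu1)
        # 1 - [Ga (b - lam) + Gb (lam - a)] / (b - a)
        assert coeffs[0] == pytest.approx(1 - (Ga * b - Gb * a) / (b - a), rel=1e-12)
        assert coeffs[1] == pytest.approx(-(Gb - Ga) / (b - a), rel=1e-12)

    def test_endpoint_reproduction(self):
        a, b, nu1 = 0.5, 16.0, 4
        for r in (4, 7, 10):
            coeffs = bernstein_target_coeffs(a, b, r, nu1)
            at_a = np.polynomial.polynomial.polyval(a, coeffs)
            at_b = np.polynomial.polynomial.polyval(b, coeffs)
            assert at_a == pytest.approx(stats.chi2.sf(a, nu1), abs=1e-10)
            assert at_b == pytest.approx(stats.chi2.sf(b, nu1), abs=1e-10)

    def test_sup_error_decreases_with_degree(self):
        a, b, nu1 = 0.0, 18.0, 4
        lam = np.linspace(a, b, 500)
        errs = []
        for r in (4, 7, 10):
            coeffs = bernstein_target_coeffs(a, b, r, nu1)
            approx = np.polynomial.polynomial.polyval(lam, coeffs)
            errs.append(np.max(np.abs(approx - stats.chi2.sf(lam, nu1))))
        # Bernstein converges slowly but monotonically in the degree
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.1


class TestQuadratureTargets:
    def test_value_at_a(self):
        a, b, nu1 = 1.5, 20.0, 4
        coeffs = quadrature_target_coeffs(a, b, 7, nu1)
        at_a = np.polynomial.polynomial.polyval(a, coeffs)
        assert at_a == pytest.approx(stats.chi2.sf(a, nu1), abs=1e-10)

    def test_density_mass_recovered(self):
        # integral of the density approximation over [a,b] ~ G(b) - G(a)
        a, b, nu1 = 1.0, 16.0, 4
        truth = stats.chi2.cdf(b, nu1) - stats.chi2.cdf(a, nu1)
        errs = []
        for r, tol in ((4, 0.2), (7, 0.01), (10, 0.001)):
            coeffs = quadrature_target_coeffs(a, b, r, nu1)
            at_b = np.polynomial.polynomial.polyval(b, coeffs)
            mass = (1 - stats.chi2.cdf(a, nu1)) - at_b
            errs.append(abs(mass - truth))
            assert mass == pytest.approx(truth, abs=tol)
        assert errs[0] > errs[1] > errs[2]

    def test_beats_bernstein_above_mode(self):
        # on [4, 30] with nu1=4 the quadrature approximation is more accurate
        a, b, nu1, r = 4.0, 30.0, 4, 7
        lam = np.linspace(a, b, 500)
        truth = stats.chi2.sf(lam, nu1)
        qc = quadrature_target_coeffs(a, b, r, nu1)
        bc = bernstein_target_coeffs(a, b, r, nu1)
        q_err = np.max(np.abs(np.polynomial.polynomial.polyval(lam, qc) - truth))
        b_err = np.max(np.abs(np.polynomial.polynomial.polyval(lam, bc) - truth))
        assert q_err < b_err


class TestSolveMatched:
    def test_degree_zero(self):
        d = Dims(4, 20)
        out = solve_matched_coeffs([0.7], [f0_moment_poly(0, d)])
        assert out[0] == pytest.approx(0.7)

    @pytest.mark.parametrize("nu1", [2, 4, 8])
    @pytest.mark.parametrize("nu2,r", [(10, 4), (20, 4), (20, 7), (80, 4), (80, 7), (80, 10)])
    def test_roundtrip_residual(self, nu1, nu2, r):
        d = Dims(nu1, nu2)
        ep = select_endpoints(3.0, d)
        moments = [f0_moment_poly(i, d) for i in range(r + 1)]
        for family, build in (("bernstein", bernstein_target_coeffs),
                              ("quadrature", quadrature_target_coeffs)):
            target = build(ep.a, ep.b, r, nu1)
            matched = solve_matched_coeffs(target, moments)
            recon = np.zeros(r + 1)
            for i, mp in enumerate(moments):
                for j, c in enumerate(mp.coeffs):
                    recon[j] += matched[i] * c
            assert np.max(np.abs(recon - target)) <= 1e-9 * max(1.0, np.max(np.abs(target)))

    def test_monte_carlo_unbiasedness_of_matched_poly(self, rng):
        # fixed coefficients: E(sum b_i F0^i) = sum a_i lam^i exactly
        d = Dims(4, 20)
        lam, r = 2.0, 7
        a, b = 1.0, 18.0
        target = quadrature_target_coeffs(a, b, r, d.nu1)
        moments = [f0_moment_poly(i, d) for i in range(r + 1)]
        matched = solve_matched_coeffs(target, moments)
        F0 = draw_F0(rng, lam, d, 100_000)
        vals = np.polynomial.polynomial.polyval(F0, matched)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        expected = np.polynomial.polynomial.polyval(lam, target)
        assert vals.mean() == pytest.approx(expected, abs=3 * se)


class TestPolynomialEstimate:
    def test_deterministic(self):
        d = Dims(4, 24)
        v1 = polynomial_estimate(1.3, d, 7, "quadrature").value
        v2 = polynomial_estimate(1.3, d, 7, "quadrature").value
        assert v1 == v2

    def test_out_of_range_small_lambda0(self):
        # quadrature estimates exceed 1 for some small observed indices
        d = Dims(4, 24)
        grid = np.linspace(0.02, 0.5, 40)
        for r in (4, 7):
            vals = polynomial_batch(d.n * d.nu2 * grid / ((d.n - 1) * d.nu1), d, r, "quadrature")
            assert np.any(vals > 1.0)

    def test_out_of_range_large_lambda0(self):
        d = Dims(4, 24)
        grid = np.linspace(12.0, 30.0, 60)
        for r in (4, 7):
            vals = polynomial_batch(d.n * d.nu2 * grid / ((d.n - 1) * d.nu1), d, r, "quadrature")
            assert np.any(vals < 0.0)

    def test_clip_option(self):
        d = Dims(4, 24)
        est = polynomial_estimate(0.4, d, 7, "quadrature", clip=True)
        assert 0.0 <= est.value <= 1.0
        assert est.notes["raw_value"] > 1.0 and est.notes["clipped"]

    def test_degree_constraint(self):
        with pytest.raises(UnsupportedConfigError):
            polynomial_estimate(1.0, Dims(4, 10), 7, "quadrature")
        with pytest.raises(UnsupportedConfigError):
            polynomial_batch(np.array([1.0]), Dims(2, 20), 10, "bernstein")

    def test_unknown_family(self):
        with pytest.raises(DomainError):
            polynomial_estimate(1.0, Dims(4, 20), 4, "chebyshev")

    def test_build_approx_fields(self):
        d = Dims(4, 20)
        approx = build_approx(2.0, d, 4, "bernstein")
        assert approx.a < approx.b
        assert len(approx.target_coeffs) == 5
        assert len(approx.matched_coeffs) == 5
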