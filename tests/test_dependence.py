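import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

import markovpot as mp
from markovpot.dependence import frechet_threshold

from _oracles import numeric_mixed_partial


class TestFrechetTransform:
    def test_closed_form_values(self):
        # F(x) = e^-1 maps to z = 1; F(x) = 0.5 to -1/ln 0.5 (both need a
        # censoring point below those probabilities, i.e. a high lambda_u)
        tail = mp.GPDTail(u=0.0, sigma=1.0, xi=-0.3, lambda_u=0.7)
        x1 = mp.from_frechet(1.0, tail)
        assert mp.to_frechet(x1, tail) == pytest.approx(1.0, abs=1e-9)
        z_half = -1.0 / math.log(0.5)
        assert z_half == pytest.approx(1.4427, abs=1e-4)
        x2 = mp.from_frechet(z_half, tail)
        assert mp.to_frechet(x2, tail) == pytest.approx(z_half, abs=1e-9)

    def test_unit_rate_transform_matches_exceedance_cdf(self):
        # with lambda = 1 the transform is z = -1/log H(x): H = 0.9 -> 9.491
        tail = mp.GPDTail(u=0.0, sigma=1.0, xi=-0.3, lambda_u=1.0)
        x = mp.gpd_quantile(0.9, tail)
        z = mp.to_frechet(x, tail, frechet_rate="unit")
        assert z == pytest.approx(-1.0 / math.log(0.9), abs=1e-9)
        assert z == pytest.approx(9.491, abs=1e-3)

    def test_round_trip_across_support(self, small_tail):
        x = np.linspace(small_tail.u + 1e-6, small_tail.upper - 1e-6, 200)
        z = mp.to_frechet(x, small_tail)
        np.testing.assert_allclose(mp.from_frechet(z, small_tail), x, atol=1e-9)

    def test_strictly_increasing(self, small_tail):
        x = np.linspace(small_tail.u, small_tail.upper - 1e-9, 100)
        z = mp.to_frechet(x, small_tail)
        assert np.all(np.diff(z) > 0)

    def test_censored_values_map_to_threshold_image(self, small_tail):
        z_u = frechet_threshold(small_tail)
        assert z_u == pytest.approx(-1.0 / math.log1p(-small_tail.lambda_u))
        assert mp.to_frechet(small_tail.u - 5.0, small_tail) == z_u

    def test_inverse_rejects_censored_region(self, small_tail):
        with pytest.raises(ValueError):
            mp.from_frechet(frechet_threshold(small_tail) * 0.5, small_tail)


class TestLogisticJoint:
    def test_independence_product(self):
        assert mp.logistic_joint_cdf(1.0, 1.0, 1.0) == pytest.approx(
            math.exp(-2), abs=1e-12
        )

    def test_symmetric_half_dependence(self):
        assert mp.logistic_joint_cdf(1.0, 1.0, 0.5) == pytest.approx(
            math.exp(-math.sqrt(2)), abs=1e-12
        )

    def test_marginal_consistency(self):
        for a in (0.2, 0.5, 1.0):
            assert mp.logistic_joint_cdf(1.0, 1e12, a) == pytest.approx(
                math.exp(-1), abs=1e-9
            )

    def test_monotone_in_alpha_on_diagonal(self):
        vals = [mp.logistic_joint_cdf(1.0, 1.0, a) for a in (0.1, 0.4, 0.7, 1.0)]
        assert np.all(np.diff(vals) < 0)

    def test_alpha_domain_enforced(self):
        with pytest.raises(ValueError):
            mp.logistic_joint_cdf(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            mp.logistic_joint_cdf(1.0, 1.0, 1.3)

    @given(
        z1=st.floats(0.05, 50.0),
        z2=st.floats(0.05, 50.0),
        a=st.floats(0.05, 1.0),
    )
    def test_frechet_hoeffding_bounds(self, z1, z2, a):
        F1, F2 = math.exp(-1.0 / z1), math.exp(-1.0 / z2)
        G = mp.logistic_joint_cdf(z1, z2, a)
        assert max(0.0, F1 + F2 - 1.0) - 1e-12 <= G <= min(F1, F2) + 1e-12

    def test_complete_dependence_limit(self):
        # alpha -> 0: G -> exp(-1/min(z1, z2))
        G = mp.logistic_joint_cdf(1.0, 3.0, 0.01)
        assert G == pytest.approx(math.exp(-1.0), rel=1e-2)


class TestChiMeasure:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(1.0, 0.0), (0.5, 2 - math.sqrt(2)), (0.17, 2 - 2**0.17)],
    )
    def test_closed_form(self, alpha, expected):
        assert mp.chi_measure(alpha) == pytest.approx(expected, abs=1e-12)

    def test_strong_dependence_value(self):
        assert mp.chi_measure(0.17) == pytest.approx(0.875, abs=5e-3)


class TestCensoredDensity:
    def test_analytic_density_matches_numeric_mixed_partial(self):
        from markovpot.dependence import _log_density_z

        for a in (0.2, 0.5, 0.8, 1.0):
            for z1 in (0.5, 1.0, 3.0):
                for z2 in (0.7, 2.0):
                    ana = math.exp(
                        _log_density_z(math.log(z1), math.log(z2), a)
                    )
                    num = numeric_mixed_partial(z1, z2, a)
                    assert ana == pytest.approx(num, rel=1e-4)

    def test_both_below_mass_independence(self):
        tail = mp.GPDTail(u=0.0, sigma=1.0, xi=-0.3, lambda_u=0.1)
        mass = mp.censored_pair_density(-1.0, -2.0, tail, 1.0)
        assert mass == pytest.approx(0.81, abs=1e-12)  # (1 - 0.1)^2

    def test_both_below_mass_general(self, small_tail):
        a = 0.4
        expected = (1 - small_tail.lambda_u) ** (2**a)
        assert mp.censored_pair_density(
            small_tail.u - 1, small_tail.u - 2, small_tail, a
        ) == pytest.approx(expected, rel=1e-12)

    def test_independence_factorizes(self, small_tail):
        lam = small_tail.lambda_u
        for x1, x2 in [(0.3, 1.1), (0.05, 0.8)]:
            d = mp.censored_pair_density(x1, x2, small_tail, 1.0)
            prod = (
                lam * mp.gpd_pdf(x1, small_tail) * lam * mp.gpd_pdf(x2, small_tail)
            )
            assert d == pytest.approx(prod, rel=1e-8)

    def test_region_classification(self):
        assert mp.classify_region(1.0, 2.0, 0.0) == "both-above"
        assert mp.classify_region(1.0, -1.0, 0.0) == "first-above"
        assert mp.classify_region(-1.0, 1.0, 0.0) == "second-above"
        assert mp.classify_region(-1.0, -2.0, 0.0) == "both-below"

    @pytest.mark.parametrize(
        "alpha,xi", [(0.2, -0.5), (0.5, 0.0), (1.0, 0.3), (0.5, -0.5)]
    )
    def test_four_regions_sum_to_one(self, alpha, xi):
        """Quadrature oracle: total probability over the four censoring
        regions of the lag-1 pair law is 1."""
        tail = mp.GPDTail(u=0.0, sigma=1.0, xi=xi, lambda_u=0.2)
        top = tail.upper if xi < 0 else mp.gpd_quantile(1 - 1e-10, tail)
        both, _ = integrate.dblquad(
            lambda y, x: mp.censored_pair_density(x, y, tail, alpha),
            tail.u, top, tail.u, top, epsabs=1e-9, epsrel=1e-9,
        )
        first, _ = integrate.quad(
            lambda x: mp.censored_pair_density(x, tail.u - 1.0, tail, alpha),
            tail.u, top, epsabs=1e-11,
        )
        second, _ = integrate.quad(
            lambda x: mp.censored_pair_density(tail.u - 1.0, x, tail, alpha),
            tail.u, top, epsabs=1e-11,
        )
        mass = mp.censored_pair_density(tail.u - 1.0, tail.u - 2.0, tail, alpha)
        assert both + first + second + mass == pytest.approx(1.0, abs=1e-4)

    def test_conditional_cdf_is_proper(self):
        z2 = np.geomspace(1e-4, 1e6, 200)
        for a in (0.17, 0.5, 1.0):
            c = mp.logistic_conditional_cdf(z2, 1.3, a)
            assert np.all(np.diff(c) > -1e-12)
            assert c[0] < 1e-6 and c[-1] > 1 - 1e-5
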