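"""Hazard functions and frailty discretization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from frailvar import (
    GGMParams,
    FrailtyDiscretization,
    baseline_mortality_vector,
    discretize_frailty,
    gm_hazard,
    marginal_hazard,
)

P = GGMParams(a=0.02, b=0.1, c=0.005, gamma=0.2)


class TestGMHazard:
    @pytest.mark.parametrize(
        "x, z, expected",
        [
            (0.0, 1.0, 0.02 + 0.005),          # exp(0) = 1
            (0.0, 2.0, 2 * 0.02 + 0.005),      # proportional hazard
            (10.0, 1.0, 0.02 * np.e + 0.005),  # direct evaluation
        ],
    )
    def test_closed_form_values(self, x, z, expected):
        assert gm_hazard(x, z, P) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            gm_hazard(-1.0, 1.0, P)
        with pytest.raises(ValueError):
            gm_hazard(1.0, 0.0, P)

    @given(
        x=st.floats(0, 200), z=st.floats(0.01, 50),
        a=st.floats(1e-4, 0.5), b=st.floats(1e-3, 0.5), c=st.floats(0, 0.3),
    )
    @settings(max_examples=50, deadline=None)
    def test_frailty_scales_age_dependent_part(self, x, z, a, b, c):
        """Frailty multiplies exactly the age-dependent part of the hazard."""
        p = GGMParams(a=a, b=b, c=c, gamma=0.1)
        lhs = gm_hazard(x, z, p) - c
        rhs = z * (gm_hazard(x, 1.0, p) - c)
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestMarginalHazard:
    def test_starts_at_a_plus_c_for_any_gamma(self):
        for gamma in (0.0, 0.05, 0.2, 1.0):
            p = GGMParams(a=0.02, b=0.1, c=0.005, gamma=gamma)
            assert marginal_hazard(0.0, p) == pytest.approx(0.025, rel=1e-12)

    def test_homogeneous_limit_is_gompertz_makeham(self):
        p0 = GGMParams(a=0.02, b=0.1, c=0.005, gamma=0.0)
        x = np.linspace(0, 100, 31)
        np.testing.assert_allclose(
            marginal_hazard(x, p0), gm_hazard(x, 1.0, p0), rtol=1e-13
        )

    def test_plateau_limit(self):
        """Selection of the robust bounds the hazard at b/gamma + c."""
        plateau = P.b / P.gamma + P.c
        assert marginal_hazard(400.0, P) == pytest.approx(plateau, rel=1e-6)
        x = np.linspace(0, 150, 300)
        mu = marginal_hazard(x, P)
        assert np.all(np.diff(mu) > 0)  # strictly increasing before saturation
        x_far = np.linspace(0, 400, 500)
        mu_far = marginal_hazard(x_far, P)
        assert np.all(np.diff(mu_far) >= -1e-12)  # nondecreasing up to roundoff
        assert np.all(mu_far - P.c <= P.b / P.gamma + 1e-12)

    def test_survivorship_matches_frailty_mixture(self):
        """The pi-weighted mixture of conditional survivorships converges to
        the marginal survivorship as the discretization refines."""
        a, b, c, gam = P.a, P.b, P.c, P.gamma

        def mixture_surv(x, fr):
            cumhaz = fr.z * (a / b) * (np.exp(b * x) - 1.0) + c * x
            return float(fr.pi @ np.exp(-cumhaz))

        def marginal_surv(x):
            val, _ = quad(lambda t: marginal_hazard(t, P), 0, x)
            return np.exp(-val)

        xs = [10.0, 40.0, 80.0]
        errs = {}
        for g in (25, 100, 400):
            fr = discretize_frailty(gam, g)
            errs[g] = max(abs(mixture_surv(x, fr) - marginal_surv(x)) for x in xs)
        assert errs[400] < errs[100] < errs[25]
        assert errs[400] < 1e-4


class TestBaselineVector:
    def test_closed_form(self):
        mu0 = baseline_mortality_vector(GGMParams(a=0.02, b=0.1, c=0.0, gamma=0.0), 3)
        np.testing.assert_allclose(mu0, [0.02, 0.0221034, 0.0244281], rtol=1e-5)

    def test_geometric_growth_and_default_length(self):
        mu0 = baseline_mortality_vector(P)
        assert mu0.shape == (150,)
        assert mu0[0] == P.a
        np.testing.assert_allclose(mu0[1:] / mu0[:-1], np.exp(P.b), rtol=1e-12)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            baseline_mortality_vector(P, 0)


class TestDiscretizeFrailty:
    def test_degenerate_below_threshold(self):
        for gamma in (0.0, 1e-6, 9.9e-6):
            fr = discretize_frailty(gamma, g=200)
            assert fr.g == 1
            np.testing.assert_array_equal(fr.z, [1.0])
            np.testing.assert_array_equal(fr.pi, [1.0])

    def test_mean_one_and_variance(self):
        fr = discretize_frailty(0.2, g=200)
        assert fr.g == 200
        assert fr.pi @ fr.z == pytest.approx(1.0, abs=1e-12)
        assert fr.variance == pytest.approx(0.2, rel=0.02)

    @pytest.mark.parametrize("gamma", [0.05, 0.2, 1.0])
    def test_weights_are_probabilities(self, gamma):
        fr = discretize_frailty(gamma, g=150)
        assert np.all(fr.pi >= 0)
        assert fr.pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(fr.z) > 0)

    def test_refinement_consistency(self):
        """Doubling g changes the variance by ever smaller amounts (the
        refinement sequence is Cauchy), and the error against gamma shrinks
        from coarse to fine grids.  (At large g the residual error is the
        fixed q_max tail truncation, not node spacing.)"""
        for gamma in (0.1, 0.5):
            grid = (25, 50, 100, 200, 400)
            var = {g: discretize_frailty(gamma, g).variance for g in grid}
            var[800] = discretize_frailty(gamma, 800).variance
            jumps = [abs(var[2 * g] - var[g]) for g in grid]
            assert all(j2 < j1 for j1, j2 in zip(jumps, jumps[1:]))
            assert abs(var[400] - gamma) < abs(var[25] - gamma)

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            discretize_frailty(0.2, g=0)
        with pytest.raises(ValueError):
            discretize_frailty(0.2, g=10, q_min=0.5, q_max=0.1)

    def test_invalid_discretization_rejected(self):
        with pytest.raises(ValueError):
            FrailtyDiscretization(z=np.array([0.5, 1.5]), pi=np.array([0.7, 0.7]))
        with pytest.raises(ValueError):
            # mean far from 1
            FrailtyDiscretization(z=np.array([2.0, 3.0]), pi=np.array([0.5, 0.5]))
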