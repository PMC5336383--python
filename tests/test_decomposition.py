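"""Fundamental matrix, longevity moments, and the variance decomposition."""

import numpy as np
import pytest

from frailvar import (
    FrailtyDiscretization,
    GGMParams,
    build_projection_matrix,
    decompose_variance,
    discretize_frailty,
    empirical_decomposition,
    extract_age1_groups,
    fundamental_matrix,
    longevity_moments,
    longevity_moments_from_model,
    matrix_decomposition,
    monte_carlo_decomposition,
    simulate_lifetimes,
)

SINGLE = FrailtyDiscretization(z=np.array([1.0]), pi=np.array([1.0]))


def _half_survival_params():
    """Parameters giving survival probability exactly 1/2 at model age 0."""
    return GGMParams(a=np.log(2.0), b=1e-9, c=0.0, gamma=0.0)


class TestFundamentalMatrix:
    def test_zero_chain_gives_identity(self):
        p = GGMParams(a=50.0, b=1e-3, c=0.0, gamma=0.0)  # survival ~ 0
        model = build_projection_matrix(p, SINGLE, 3)
        np.testing.assert_allclose(fundamental_matrix(model), np.eye(3), atol=1e-20)

    def test_two_state_closed_form(self):
        model = build_projection_matrix(_half_survival_params(), SINGLE, 2)
        np.testing.assert_allclose(
            fundamental_matrix(model), [[1.0, 0.0], [0.5, 1.0]], rtol=1e-12
        )

    def test_equals_neumann_series(self, study_params):
        fr = discretize_frailty(0.4, g=3)
        model = build_projection_matrix(study_params, fr, 6)
        U = model.U_tilde.toarray()
        series = sum(np.linalg.matrix_power(U, t) for t in range(7))
        np.testing.assert_allclose(fundamental_matrix(model), series, rtol=1e-12)

    def test_unit_diagonal(self, study_params):
        model = build_projection_matrix(study_params, discretize_frailty(0.2, 4), 5)
        np.testing.assert_allclose(np.diag(fundamental_matrix(model)), 1.0)


class TestLongevityMoments:
    def test_deterministic_chain_has_zero_variance(self):
        p = GGMParams(a=1e-300, b=1e-3, c=0.0, gamma=0.0)  # survival ~ 1
        model = build_projection_matrix(p, SINGLE, 5)
        eta1, _, V = longevity_moments(fundamental_matrix(model))
        np.testing.assert_allclose(eta1, [5, 4, 3, 2, 1], rtol=1e-12)
        np.testing.assert_allclose(V, 0.0, atol=1e-10)

    def test_bernoulli_closed_form(self):
        """omega=2 with survival 1/2: longevity is 1 + Bernoulli(1/2)."""
        model = build_projection_matrix(_half_survival_params(), SINGLE, 2)
        eta1, eta2, V = longevity_moments(fundamental_matrix(model))
        np.testing.assert_allclose(eta1, [1.5, 1.0], rtol=1e-12)
        np.testing.assert_allclose(V, [0.25, 0.0], atol=1e-12)

    def test_triangular_solve_path_matches_dense(self, study_params):
        fr = discretize_frailty(0.2, g=6)
        model = build_projection_matrix(study_params, fr, 12)
        dense = longevity_moments(fundamental_matrix(model))
        fast = longevity_moments_from_model(model)
        for d, f in zip(dense, fast):
            np.testing.assert_allclose(d, f, rtol=1e-10)

    def test_matches_monte_carlo(self, study_params, study_frailty):
        """Matrix-model mean/variance for age class 1 vs simulated lifetimes."""
        model = build_projection_matrix(study_params, study_frailty, 150)
        eta1, _, V = longevity_moments_from_model(model)
        means, variances = extract_age1_groups(eta1, V, 150, study_frailty.g)
        mix_mean = study_frailty.pi @ means
        n = 100_000
        lt = simulate_lifetimes(study_params, study_frailty, n, omega=150, seed=11)
        se_mean = lt.std(ddof=1) / np.sqrt(n)
        assert abs(lt.mean() - mix_mean) < 3 * se_mean


class TestExtractAge1Groups:
    def test_takes_first_age_block(self):
        # omega=2, g=2, ordering (age1 f1, age1 f2, age2 f1, age2 f2)
        eta1 = np.array([11.0, 21.0, 12.0, 22.0])
        V = np.array([1.0, 2.0, 3.0, 4.0])
        means, variances = extract_age1_groups(eta1, V, omega=2, g=2)
        np.testing.assert_array_equal(means, [11.0, 21.0])
        np.testing.assert_array_equal(variances, [1.0, 2.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            extract_age1_groups(np.ones(5), np.ones(5), omega=2, g=2)


class TestDecomposeVariance:
    def test_pure_heterogeneity(self):
        d = decompose_variance([2.0, 4.0], [0.0, 0.0], [0.5, 0.5])
        assert d.v_between == pytest.approx(1.0)
        assert d.v_within == 0.0
        assert d.fraction_heterogeneity == pytest.approx(1.0)
        assert d.mixture_mean == pytest.approx(3.0)

    def test_identical_groups_have_no_between_variance(self):
        d = decompose_variance([3.0, 3.0, 3.0], [1.0, 2.0, 3.0], [0.2, 0.3, 0.5])
        assert d.v_between == 0.0
        assert d.fraction_heterogeneity == 0.0
        assert d.v_within == pytest.approx(0.2 + 0.6 + 1.5)

    def test_single_group(self):
        d = decompose_variance([5.0], [2.5], [1.0])
        assert d.v_between == 0.0
        assert d.v_total == pytest.approx(2.5)

    def test_degenerate_chain_reports_nan_fraction(self):
        d = decompose_variance([3.0], [0.0], [1.0])
        assert np.isnan(d.fraction_heterogeneity)

    def test_rejects_unnormalized_pi(self):
        with pytest.raises(ValueError, match="normalized"):
            decompose_variance([1.0, 2.0], [0.1, 0.1], [0.5, 0.6])

    def test_permutation_invariance(self, rng):
        means = rng.random(6) * 10
        variances = rng.random(6)
        pi = rng.dirichlet(np.ones(6))
        d1 = decompose_variance(means, variances, pi)
        perm = rng.permutation(6)
        d2 = decompose_variance(means[perm], variances[perm], pi[perm])
        assert d1.v_within == pytest.approx(d2.v_within, rel=1e-12)
        assert d1.v_between == pytest.approx(d2.v_between, rel=1e-12)


class TestMatrixVsMonteCarlo:
    def test_gamma_increases_heterogeneity_share(self, study_params):
        """With (a, b, c) fixed, larger frailty variance shifts longevity
        variance from stochasticity toward heterogeneity."""
        fracs, betweens = [], []
        for gamma in (0.05, 0.1, 0.2, 0.4):
            p = GGMParams(a=0.02, b=0.1, c=0.005, gamma=gamma, start_age=40)
            d = matrix_decomposition(p, discretize_frailty(gamma, 100), 150)
            fracs.append(d.fraction_heterogeneity)
            betweens.append(d.v_between)
        assert all(f2 > f1 for f1, f2 in zip(fracs, fracs[1:]))
        assert all(b2 > b1 for b1, b2 in zip(betweens, betweens[1:]))

    def test_empirical_total_law_holds_exactly(self, study_params, study_frailty):
        lt, lab = simulate_lifetimes(
            study_params, study_frailty, 20_000, seed=7, return_labels=True
        )
        d = empirical_decomposition(lt, lab, study_frailty.g)
        pooled = lt.astype(float).var()  # population variance
        assert d.v_total == pytest.approx(pooled, rel=1e-10)

    def test_monte_carlo_reproducible(self, study_params, study_frailty):
        d1 = monte_carlo_decomposition(study_params, study_frailty, 150, 5000, seed=2)
        d2 = monte_carlo_decomposition(study_params, study_frailty, 150, 5000, seed=2)
        assert d1.v_total == d2.v_total
        assert d1.fraction_heterogeneity == d2.fraction_heterogeneity

    def test_homogeneous_empirical_between_is_zero(self, homogeneous_params):
        d = monte_carlo_decomposition(homogeneous_params, SINGLE, 150, 10_000, seed=4)
        assert d.v_between == 0.0
        assert d.fraction_heterogeneity == 0.0
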