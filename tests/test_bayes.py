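import numpy as np
import pytest
from scipy import stats

from tldose import (
    LikelihoodSpec,
    PosteriorGrid,
    PriorK,
    PriorTheta,
    classical_doses,
    cramer_rao_sigma,
    estimate_from_posterior,
    likelihood_density,
    posterior_mean,
    posterior_mode,
    posterior_option1,
    posterior_option2,
    posterior_option3,
)
from tldose.errors import (
    DegenerateLikelihoodError,
    GridCoverageError,
    MultimodalPosteriorWarning,
)
from tldose.scenarios import scenario

from conftest import k_prior_for, spec_for, theta_prior_for

S70 = scenario("70b30g")
SPEC70 = spec_for(S70)


def gaussian_grid(mean: float, sd: float, n: int = 4001, span: float = 8.0) -> PosteriorGrid:
    """An exactly Gaussian posterior tabulated on a uniform grid."""
    x = np.linspace(mean - span * sd, mean + span * sd, n)
    p = stats.norm.pdf(x, mean, sd)
    return PosteriorGrid(x, p / np.trapezoid(p, x))


class TestLikelihoodDensity:
    def test_peak_at_matching_dose(self):
        theta, k = 0.5, 8.17e-7
        d_match = SPEC70.n_uncovered * theta * k
        val = likelihood_density(d_match, "beta", theta, k, SPEC70)
        assert val == pytest.approx(1.0 / (SPEC70.sigma_n * np.sqrt(2 * np.pi)), rel=1e-12)

    def test_zero_dose_beta(self):
        val = likelihood_density(0.0, "beta", 0.3, 8.17e-7, SPEC70)
        expected = np.exp(-(SPEC70.n_uncovered**2) / (2 * SPEC70.sigma_n**2)) / (
            SPEC70.sigma_n * np.sqrt(2 * np.pi)
        )
        assert val == pytest.approx(expected, rel=1e-9)

    def test_matches_direct_gaussian_pdf(self):
        spec = LikelihoodSpec(1_197_509, 50_000)
        val = likelihood_density(0.5, "beta", 0.5, 8.17e-7, spec)
        implied = 0.5 / (0.5 * 8.17e-7)
        assert val == pytest.approx(
            stats.norm.pdf(implied, 1_197_509, 50_000), rel=1e-12
        )

    def test_degenerate_theta_rejected(self):
        with pytest.raises(DegenerateLikelihoodError):
            likelihood_density(0.5, "beta", 0.0, 8.17e-7, SPEC70)
        with pytest.raises(DegenerateLikelihoodError):
            likelihood_density(0.5, "gamma", 1.0, 9.29e-7, SPEC70)


class TestPosteriorOptions:
    @pytest.mark.parametrize("option", [1, 2, 3])
    def test_normalised(self, option):
        pt, pk = theta_prior_for(S70), k_prior_for("beta")
        if option == 1:
            grid = posterior_option1("beta", SPEC70, pt, pk.k_hat)
        elif option == 2:
            grid = posterior_option2("beta", SPEC70, S70.theta, pk)
        else:
            grid = posterior_option3("beta", SPEC70, pt, pk)
        assert np.trapezoid(grid.density, grid.dose_grid) == pytest.approx(1.0, abs=1e-9)
        assert np.all(grid.density >= 0)

    def test_delta_theta_prior_limit_recovers_classical(self, cal_gamma, cal_beta):
        gamma, beta = classical_doses(S70.n_uncovered, S70.theta, cal_gamma, cal_beta)
        grid = posterior_option1(
            "beta", SPEC70, PriorTheta(S70.theta, 1e-8), cal_beta.k_hat
        )
        assert abs(posterior_mode(grid) - beta.value) <= grid.step

    def test_delta_k_prior_limit_recovers_classical(self, cal_beta):
        _, beta = classical_doses(S70.n_uncovered, S70.theta, 9.29e-7, cal_beta)
        grid = posterior_option2(
            "beta", SPEC70, S70.theta, PriorK(cal_beta.k_hat, 1e-6 * cal_beta.k_hat)
        )
        assert abs(posterior_mode(grid) - beta.value) <= grid.step

    def test_beta_gamma_symmetry(self):
        # swapping component labels and theta -> 1 - theta maps one marginal
        # onto the other exactly (same k)
        k = 8.17e-7
        sigma = 0.02
        dose = np.linspace(0.0, 2.4, 2049)
        pb = posterior_option1("beta", SPEC70, PriorTheta(0.3, sigma), k, dose_grid=dose)
        pg = posterior_option1("gamma", SPEC70, PriorTheta(0.7, sigma), k, dose_grid=dose)
        np.testing.assert_allclose(pb.density, pg.density, rtol=1e-10, atol=1e-12)

    def test_mode_insensitive_to_sigma_n_choice_option1(self):
        # the count spread is a convention, not a measurement; the reported
        # mode must not move at the 0.001 mSv reporting resolution when the
        # spread is varied over a factor of five
        modes = []
        for frac in (0.02, 0.05, 0.10):
            spec = LikelihoodSpec(S70.n_uncovered, frac * S70.n_uncovered)
            grid = posterior_option1("gamma", spec, theta_prior_for(S70), 9.29e-7)
            modes.append(posterior_mode(grid))
        assert max(modes) - min(modes) < 1e-3
        assert len({round(m, 3) for m in modes}) == 1

    def test_option2_mean_mode_gap_small_at_calibration_spreads(self):
        grid = posterior_option2("beta", SPEC70, S70.theta, k_prior_for("beta"))
        mode = posterior_mode(grid)
        assert abs(posterior_mean(grid) - mode) / mode < 0.005

    def test_option3_reduces_to_option2_with_degenerate_theta(self):
        pk = k_prior_for("beta")
        g2 = posterior_option2("beta", SPEC70, S70.theta, pk)
        g3 = posterior_option3(
            "beta", SPEC70, PriorTheta(S70.theta, 1e-12), pk, dose_grid=g2.dose_grid
        )
        assert np.max(np.abs(g3.density - g2.density)) <= 1e-6 * g2.density.max()

    def test_option3_reduces_to_option1_with_degenerate_k(self):
        pt = theta_prior_for(S70)
        g1 = posterior_option1("beta", SPEC70, pt, 8.17e-7)
        g3 = posterior_option3(
            "beta", SPEC70, pt, PriorK(8.17e-7, 1e-18), dose_grid=g1.dose_grid
        )
        assert np.max(np.abs(g3.density - g1.density)) <= 1e-6 * g1.density.max()

    def test_grid_missing_mass_rejected(self):
        dose = np.linspace(3.0, 4.0, 512)  # posterior mass sits near 0.77
        with pytest.raises(GridCoverageError):
            posterior_option2("beta", SPEC70, S70.theta, k_prior_for("beta"), dose_grid=dose)


class TestPosteriorSummaries:
    def test_mode_of_tabulated_gaussian(self):
        grid = gaussian_grid(0.75, 0.02)
        assert posterior_mode(grid) == pytest.approx(0.75, abs=1e-6 * 0.02)

    def test_mode_stable_under_grid_refinement(self):
        pk = k_prior_for("beta")
        coarse = posterior_option2("beta", SPEC70, S70.theta, pk, n_dose=2048)
        fine = posterior_option2("beta", SPEC70, S70.theta, pk, n_dose=4096)
        assert abs(posterior_mode(coarse) - posterior_mode(fine)) < 1e-4

    def test_boundary_mode_rejected(self):
        x = np.linspace(0.0, 1.0, 101)
        p = np.exp(2.0 * x)
        with pytest.raises(GridCoverageError):
            posterior_mode(PosteriorGrid(x, p / np.trapezoid(p, x)))

    def test_multimodal_density_warns(self):
        x = np.linspace(0.0, 1.0, 2001)
        p = stats.norm.pdf(x, 0.3, 0.03) + 0.8 * stats.norm.pdf(x, 0.7, 0.03)
        grid = PosteriorGrid(x, p / np.trapezoid(p, x))
        with pytest.warns(MultimodalPosteriorWarning):
            mode = posterior_mode(grid)
        assert mode == pytest.approx(0.3, abs=1e-3)

    def test_cramer_rao_exact_on_gaussian(self):
        sd = 0.0173
        grid = gaussian_grid(0.5, sd)
        assert cramer_rao_sigma(grid) == pytest.approx(sd, rel=1e-3)

    def test_reported_uncertainty_is_doubled_cramer_rao(self):
        grid = posterior_option2("beta", SPEC70, S70.theta, k_prior_for("beta"))
        est = estimate_from_posterior(grid, "beta", 2)
        assert est.uncertainty_2sigma == pytest.approx(2 * cramer_rao_sigma(grid), rel=1e-12)
        assert est.method == "bayes-opt2"

    def test_option2_width_exceeds_pure_likelihood_width(self, cal_beta):
        # marginalising over k inflates the width beyond sigma_N * theta * k
        grid = posterior_option2("beta", SPEC70, S70.theta, k_prior_for("beta"))
        assert cramer_rao_sigma(grid) >= SPEC70.sigma_n * S70.theta * cal_beta.k_hat

class TestPosteriorGridInvariants:
    def test_unnormalised_density_rejected(self):
        x = np.linspace(0, 1, 11)
        with pytest.raises(ValueError):
            PosteriorGrid(x, np.full(11, 2.0))

    def test_negative_density_rejected(self):
        x = np.linspace(0, 1, 11)
        p = np.full(11, 1.0)
        p[3] = -0.1
        with pytest.raises(ValueError):
            PosteriorGrid(x, p)

    def test_nonincreasing_grid_rejected(self):
        x = np.zeros(11)
        with pytest.raises(ValueError):
            PosteriorGrid(x, np.full(11, 1.0))
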