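import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tldose import (
    Component,
    CountDecomposition,
    SourceSpec,
    classical_doses,
    decompose,
    propagate_uncertainty,
    solve_pair,
    theta_of,
)
from tldose.errors import (
    ClampedBetaWarning,
    NegativeBetaError,
    NegativeGammaError,
    UndefinedThetaError,
)

SR90 = SourceSpec(beta_transmission=0.25)


class TestSolvePair:
    def test_closed_form(self):
        d = solve_pair(850_000, 1_000_000, SR90)
        assert d.n_beta == pytest.approx(200_000, rel=1e-12)
        assert d.n_gamma == pytest.approx(800_000, rel=1e-12)

    def test_pure_gamma_when_counts_equal(self):
        d = solve_pair(5e5, 5e5, SR90)
        assert d.n_beta == 0.0
        assert d.n_gamma == 5e5

    def test_pure_beta_at_transmission_ratio(self):
        d = solve_pair(0.25 * 1e6, 1e6, SR90)
        assert d.n_gamma == pytest.approx(0.0, abs=1e-6)
        assert d.n_beta == pytest.approx(1e6, rel=1e-12)

    def test_zero_transmission_reduces_to_difference(self):
        d = solve_pair(3e5, 1e6, SourceSpec(beta_transmission=0.0))
        assert d.n_beta == pytest.approx(7e5, rel=1e-12)

    def test_covered_above_uncovered_rejected(self):
        with pytest.raises(NegativeBetaError):
            solve_pair(1.01e6, 1e6, SR90)

    def test_small_negative_beta_clamped_on_request(self):
        with pytest.warns(ClampedBetaWarning):
            d = solve_pair(1.01e6, 1e6, SR90, sigma_n=5e4, clamp_small_negative=True)
        assert d.n_beta == 0.0
        assert d.n_gamma == 1e6

    def test_large_negative_beta_not_clamped(self):
        with pytest.raises(NegativeBetaError):
            solve_pair(1.5e6, 1e6, SR90, sigma_n=5e4, clamp_small_negative=True)

    def test_beam_inconsistent_with_transmission_rejected(self):
        # implied beta exceeds uncovered counts -> negative gamma
        with pytest.raises(NegativeGammaError):
            solve_pair(0.1e6, 1e6, SR90)


class TestThetaAndDecompose:
    @pytest.mark.parametrize(
        "n_beta, n_uncovered, expected",
        [
            (148_736, 1_121_619, 0.13261),
            (944_498, 1_313_880, 0.71886),
            (0, 123_456, 0.0),
        ],
    )
    def test_theta_values(self, n_beta, n_uncovered, expected):
        d = CountDecomposition(n_uncovered - n_beta, n_beta, n_uncovered)
        assert theta_of(d) == pytest.approx(expected, abs=5e-6)

    def test_theta_undefined_for_zero_counts(self):
        with pytest.raises(UndefinedThetaError):
            theta_of(CountDecomposition(0.0, 0.0, 0.0))

    @pytest.mark.parametrize(
        "n_uncovered, theta, n_beta, n_gamma",
        [
            (1_121_619, 0.132608, 148_736, 972_883),
            (1_294_239, 0.895630, 1_159_158, 135_081),
        ],
    )
    def test_decompose_reproduces_validation_splits(
        self, n_uncovered, theta, n_beta, n_gamma
    ):
        # theta is quoted to 6 decimals: splits land within ~2 counts
        d = decompose(n_uncovered, theta)
        assert d.n_beta == pytest.approx(n_beta, abs=2.0)
        assert d.n_gamma == pytest.approx(n_gamma, abs=2.0)

    def test_decompose_boundaries(self):
        assert decompose(1e6, 1.0).n_gamma == 0.0
        assert decompose(1e6, 0.0).n_beta == 0.0
        with pytest.raises(ValueError):
            decompose(1e6, 1.2)

    @given(
        theta=st.floats(min_value=0, max_value=1),
        n_uncovered=st.floats(min_value=1.0, max_value=1e7),
    )
    def test_round_trip(self, theta, n_uncovered):
        assert theta_of(decompose(n_uncovered, theta)) == pytest.approx(
            theta, abs=1e-12
        )

    @given(
        frac=st.floats(min_value=0.0, max_value=1.0),
        n_uncovered=st.floats(min_value=1e3, max_value=1e7),
    )
    def test_solve_then_recompose_is_consistent(self, frac, n_uncovered):
        n_covered = n_uncovered * (0.25 + 0.75 * (1 - frac))  # beta fraction = frac
        d = solve_pair(n_covered, n_uncovered, SR90)
        d2 = decompose(n_uncovered, theta_of(d))
        assert d2.n_beta == pytest.approx(d.n_beta, rel=1e-9, abs=1e-6)
        assert d2.n_gamma == pytest.approx(d.n_gamma, rel=1e-9, abs=1e-6)


class TestClassicalDoses:
    def test_validation_scenarios_to_three_decimals(self, scenario, cal_gamma, cal_beta):
        gamma, beta = classical_doses(
            scenario.n_uncovered, scenario.theta, cal_gamma, cal_beta
        )
        assert round(beta.value, 3) == scenario.d_beta_classical
        assert round(gamma.value, 3) == scenario.d_gamma_classical

    def test_zero_theta_gives_zero_beta_dose(self, cal_gamma, cal_beta):
        gamma, beta = classical_doses(1e6, 0.0, cal_gamma, cal_beta)
        assert beta.value == 0.0
        assert gamma.value == pytest.approx(1e6 * cal_gamma.k_hat, rel=1e-12)

    @given(
        theta=st.floats(min_value=0, max_value=1),
        n_uncovered=st.floats(min_value=1e3, max_value=1e7),
    )
    def test_dose_additivity(self, theta, n_uncovered):
        kg, kb = 9.29e-7, 8.17e-7
        gamma, beta = classical_doses(n_uncovered, theta, kg, kb)
        assert gamma.value / kg + beta.value / kb == pytest.approx(
            n_uncovered, rel=1e-12
        )


class TestPropagateUncertainty:
    def test_zero_sigmas_give_zero(self):
        assert propagate_uncertainty(1e6, 0, 0.5, 0, 8e-7, 0, Component.BETA) == 0.0

    def test_single_term_reduction(self):
        n_u, theta, k, sigma_n = 1e6, 0.3, 8.17e-7, 5e4
        u = propagate_uncertainty(n_u, sigma_n, theta, 0, k, 0, Component.BETA)
        assert u == pytest.approx(2 * theta * k * sigma_n, rel=1e-12)

    @pytest.mark.parametrize("component", [Component.BETA, Component.GAMMA])
    def test_agrees_with_sampling_oracle_at_small_sigmas(self, component):
        # independent oracle: empirical sd of 1e5 draws pushed through the
        # dose map, at <= 5% relative input spreads
        rng = np.random.default_rng(1234)
        n_u, theta, k = 1.2e6, 0.45, 8.17e-7
        sigma_n, sigma_theta, sigma_k = 0.03 * n_u, 0.04 * theta, 0.05 * k
        n = rng.normal(n_u, sigma_n, 100_000)
        th = rng.normal(theta, sigma_theta, 100_000)
        kk = rng.normal(k, sigma_k, 100_000)
        g = th if component is Component.BETA else 1.0 - th
        mc_2sd = 2 * np.std(n * g * kk, ddof=1)
        u = propagate_uncertainty(
            n_u, sigma_n, theta, sigma_theta, k, sigma_k, component
        )
        assert u == pytest.approx(mc_2sd, rel=0.05)
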