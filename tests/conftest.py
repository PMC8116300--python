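import hypothesis
import pytest

from tldose import LikelihoodSpec, PriorK, PriorTheta
from tldose.scenarios import (
    CAL_BETA,
    CAL_GAMMA,
    SCENARIOS,
    SIGMA_N_FRACTION,
    SIGMA_THETA_FRACTION,
)

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def cal_gamma():
    return CAL_GAMMA


@pytest.fixture(scope="session")
def cal_beta():
    return CAL_BETA


def spec_for(scenario) -> LikelihoodSpec:
    """Likelihood spec under the validation convention sigma_N = 5% of N_U."""
    return LikelihoodSpec(
        n_uncovered=scenario.n_uncovered,
        sigma_n=SIGMA_N_FRACTION * scenario.n_uncovered,
    )


def theta_prior_for(scenario) -> PriorTheta:
    """Theta prior under the validation convention sigma_theta = 1% of theta-hat."""
    return PriorTheta(
        theta_hat=scenario.theta,
        sigma_theta=SIGMA_THETA_FRACTION * scenario.theta,
    )


def k_prior_for(component) -> PriorK:
    from tldose import Component

    cal = CAL_BETA if Component(component) is Component.BETA else CAL_GAMMA
    return PriorK(k_hat=cal.k_hat, sigma_k=cal.sd)


@pytest.fixture(params=[s.label for s in SCENARIOS])
def scenario(request):
    from tldose.scenarios import scenario as lookup

    return lookup(request.param)
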