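"""Bundled validation campaign: calibration factors and five mixed-field exposures.

These are the published measurements the toolkit validates against: MCP-N
(LiF:Mg,Cu,P) pellet batches calibrated with 137Cs gamma and 90Sr/90Y beta
sources, then exposed to five mixed beta-gamma fields of ~1 mSv total with
beta fractions from 10% to 90%.  All counts are background-corrected batch
means; reference doses are the delivered component doses.

The validation convention for the statistical engines, where the campaign
itself fixes no value, is sigma_N = 5% of N_U and sigma_theta = 1% of
theta-hat (posterior modes are insensitive to both; see the tests).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import CalibrationFactor, Component, Position, SourceSpec

__all__ = [
    "CAL_GAMMA",
    "CAL_BETA",
    "CAL_BETA_COVERED",
    "SOURCE_SR90",
    "SIGMA_N_FRACTION",
    "SIGMA_THETA_FRACTION",
    "MixedFieldScenario",
    "SCENARIOS",
    "BAYES_REFERENCE",
    "MC_REFERENCE",
]

#: Gamma calibration factor used for gamma doses (137Cs campaign).
CAL_GAMMA = CalibrationFactor(
    k_hat=9.29e-7, sd=0.20e-7, source="Cs-137", position=Position.COVERED,
    component=Component.GAMMA,
)

#: Beta calibration factor used for beta doses (90Sr/90Y campaign, uncovered).
CAL_BETA = CalibrationFactor(
    k_hat=8.17e-7, sd=0.28e-7, source="Sr-90/Y-90", position=Position.UNCOVERED,
    component=Component.BETA,
)

#: Covered-position beta factor (embodies the aluminium filter response).
CAL_BETA_COVERED = CalibrationFactor(
    k_hat=2.88e-6, sd=0.16e-6, source="Sr-90/Y-90", position=Position.COVERED,
    component=Component.BETA,
)

#: The 90Sr/90Y source: 25% of beta counts pass the 1 mm aluminium filter.
SOURCE_SR90 = SourceSpec(name="Sr-90/Y-90", beta_transmission=0.25)

#: Validation convention: count spread as a fraction of N_U.
SIGMA_N_FRACTION = 0.05
#: Validation convention: theta prior spread as a fraction of theta-hat.
SIGMA_THETA_FRACTION = 0.01


@dataclass(frozen=True)
class MixedFieldScenario:
    """One mixed-field exposure of the validation campaign (batch-mean counts)."""

    label: str
    n_covered: float
    n_uncovered: float
    n_beta: float
    n_gamma: float
    d_beta_ref: float
    d_gamma_ref: float
    d_beta_classical: float
    d_gamma_classical: float

    @property
    def theta(self) -> float:
        """Beta count fraction used at validation time, N_beta / N_U."""
        return self.n_beta / self.n_uncovered


SCENARIOS: tuple[MixedFieldScenario, ...] = (
    MixedFieldScenario("10b90g", 993_801, 1_121_619, 148_736, 972_883, 0.120, 0.900, 0.122, 0.904),
    MixedFieldScenario("30b70g", 856_239, 1_180_700, 410_927, 769_773, 0.313, 0.700, 0.336, 0.715),
    MixedFieldScenario("50b50g", 695_997, 1_197_509, 646_995, 550_514, 0.511, 0.500, 0.529, 0.511),
    MixedFieldScenario("70b30g", 605_507, 1_313_880, 944_498, 369_382, 0.717, 0.300, 0.772, 0.343),
    MixedFieldScenario("90b10g", 408_605, 1_294_239, 1_159_158, 135_081, 0.919, 0.100, 0.947, 0.125),
)


def scenario(label: str) -> MixedFieldScenario:
    """Look up a validation scenario by its label (e.g. ``"70b30g"``)."""
    for s in SCENARIOS:
        if s.label == label:
            return s
    raise KeyError(f"no scenario labelled {label!r}")


#: Published Bayesian central values (mSv), keyed (label, option, component).
BAYES_REFERENCE: dict[tuple[str, int, str], float] = {
    ("10b90g", 1, "beta"): 0.122, ("10b90g", 1, "gamma"): 0.904,
    ("10b90g", 2, "beta"): 0.122, ("10b90g", 2, "gamma"): 0.902,
    ("10b90g", 3, "beta"): 0.122, ("10b90g", 3, "gamma"): 0.904,
    ("30b70g", 1, "beta"): 0.336, ("30b70g", 1, "gamma"): 0.714,
    ("30b70g", 2, "beta"): 0.336, ("30b70g", 2, "gamma"): 0.714,
    ("30b70g", 3, "beta"): 0.336, ("30b70g", 3, "gamma"): 0.714,
    ("50b50g", 1, "beta"): 0.528, ("50b50g", 1, "gamma"): 0.512,
    ("50b50g", 2, "beta"): 0.528, ("50b50g", 2, "gamma"): 0.510,
    ("50b50g", 3, "beta"): 0.528, ("50b50g", 3, "gamma"): 0.512,
    ("70b30g", 1, "beta"): 0.772, ("70b30g", 1, "gamma"): 0.342,
    ("70b30g", 2, "beta"): 0.772, ("70b30g", 2, "gamma"): 0.344,
    ("70b30g", 3, "beta"): 0.772, ("70b30g", 3, "gamma"): 0.344,
    ("90b10g", 1, "beta"): 0.946, ("90b10g", 1, "gamma"): 0.126,
    ("90b10g", 2, "beta"): 0.946, ("90b10g", 2, "gamma"): 0.126,
    ("90b10g", 3, "beta"): 0.946, ("90b10g", 3, "gamma"): 0.126,
}

#: Published Monte Carlo central values (mSv), keyed (label, option, component).
MC_REFERENCE: dict[tuple[str, int, str], float] = {
    ("10b90g", 1, "beta"): 0.122, ("10b90g", 1, "gamma"): 0.904,
    ("10b90g", 2, "beta"): 0.122, ("10b90g", 2, "gamma"): 0.904,
    ("10b90g", 3, "beta"): 0.122, ("10b90g", 3, "gamma"): 0.903,
    ("30b70g", 1, "beta"): 0.336, ("30b70g", 1, "gamma"): 0.715,
    ("30b70g", 2, "beta"): 0.336, ("30b70g", 2, "gamma"): 0.715,
    ("30b70g", 3, "beta"): 0.336, ("30b70g", 3, "gamma"): 0.715,
    ("50b50g", 1, "beta"): 0.529, ("50b50g", 1, "gamma"): 0.511,
    ("50b50g", 2, "beta"): 0.528, ("50b50g", 2, "gamma"): 0.511,
    ("50b50g", 3, "beta"): 0.529, ("50b50g", 3, "gamma"): 0.511,
    ("70b30g", 1, "beta"): 0.772, ("70b30g", 1, "gamma"): 0.343,
    ("70b30g", 2, "beta"): 0.772, ("70b30g", 2, "gamma"): 0.343,
    ("70b30g", 3, "beta"): 0.772, ("70b30g", 3, "gamma"): 0.343,
    ("90b10g", 1, "beta"): 0.947, ("90b10g", 1, "gamma"): 0.125,
    ("90b10g", 2, "beta"): 0.947, ("90b10g", 2, "gamma"): 0.125,
    ("90b10g", 3, "beta"): 0.947, ("90b10g", 3, "gamma"): 0.126,
}
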