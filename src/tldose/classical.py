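"""Algebraic two-pellet decomposition of mixed beta-gamma counts and doses.

The covered pellet registers the full gamma signal but only a fraction ``t``
of the beta signal; the uncovered pellet registers both in full:

    N_C = N_gamma + t * N_beta
    N_U = N_gamma + N_beta

Solving the pair gives the component counts, the beta count fraction
``theta = N_beta / N_U``, and finally the component doses

    D_gamma = N_U * (1 - theta) * k_gamma
    D_beta  = N_U * theta * k_beta

Uncertainties are combined to first order (exact differential) and reported
doubled (k = 2 convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .core import CalibrationFactor, Component, DoseEstimate, SourceSpec
from .errors import (
    ClampedBetaWarning,
    NegativeBetaError,
    NegativeGammaError,
    UndefinedThetaError,
)

__all__ = [
    "BeamComposition",
    "CountDecomposition",
    "solve_pair",
    "theta_of",
    "theta_uncertainty",
    "decompose",
    "classical_doses",
    "propagate_uncertainty",
]


@dataclass(frozen=True)
class BeamComposition:
    """The beta fraction of uncovered counts, theta, as value +/- 1-sigma."""

    theta_hat: float
    sigma_theta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_hat <= 1.0:
            raise ValueError(f"theta_hat must be in [0, 1], got {self.theta_hat}")
        if not self.sigma_theta >= 0:
            raise ValueError(f"sigma_theta must be >= 0, got {self.sigma_theta}")


@dataclass(frozen=True)
class CountDecomposition:
    """Uncovered counts split into gamma and beta contributions."""

    n_gamma: float
    n_beta: float
    n_uncovered: float

    def __post_init__(self) -> None:
        if self.n_gamma < 0 or self.n_beta < 0 or self.n_uncovered < 0:
            raise ValueError("count components must be nonnegative")
        total = self.n_gamma + self.n_beta
        tol = 1e-9 * max(1.0, self.n_uncovered)
        if abs(total - self.n_uncovered) > tol:
            raise ValueError(
                f"n_gamma + n_beta = {total} != n_uncovered = {self.n_uncovered}"
            )


def solve_pair(
    n_covered: float,
    n_uncovered: float,
    source: SourceSpec,
    *,
    sigma_n: float = 0.0,
    clamp_small_negative: bool = False,
) -> CountDecomposition:
    """Solve the covered/uncovered count pair for the component counts.

    With ``t = source.beta_transmission``:

        N_beta  = (N_U - N_C) / (1 - t)
        N_gamma = N_U - N_beta

    Parameters
    ----------
    sigma_n, clamp_small_negative
        Low-beta fields with measurement noise can give ``N_C`` slightly
        above ``N_U``.  When ``clamp_small_negative`` is set, a negative
        ``N_beta`` within ``2 * sigma_n`` of zero is clamped to 0 with a
        warning instead of raising.

    Raises
    ------
    NegativeBetaError
        If ``n_covered > n_uncovered`` (and not clamped).
    NegativeGammaError
        If the implied gamma counts are negative (beam inconsistent with t).
    """
    if not n_uncovered > 0:
        raise UndefinedThetaError("n_uncovered must be positive")
    t = source.beta_transmission
    if not t < 1.0:
        raise ValueError("beta_transmission must be < 1 for the pair to be solvable")
    n_beta = (n_uncovered - n_covered) / (1.0 - t)
    if n_beta < 0:
        if clamp_small_negative and abs(n_beta) <= 2.0 * sigma_n:
            warnings.warn(
                f"clamped small negative N_beta = {n_beta:.1f} to 0",
                ClampedBetaWarning,
                stacklevel=2,
            )
            n_beta = 0.0
        else:
            raise NegativeBetaError(
                f"covered counts {n_covered} exceed uncovered counts {n_uncovered}"
            )
    n_gamma = n_uncovered - n_beta
    if n_gamma < 0:
        raise NegativeGammaError(
            f"implied gamma counts are negative ({n_gamma:.1f}): "
            f"beam inconsistent with beta_transmission = {t}"
        )
    return CountDecomposition(n_gamma=n_gamma, n_beta=n_beta, n_uncovered=n_uncovered)


def theta_of(decomp: CountDecomposition) -> float:
    """Beta count fraction theta = N_beta / N_U of a decomposition."""
    if decomp.n_uncovered == 0:
        raise UndefinedThetaError("theta undefined for zero uncovered counts")
    return decomp.n_beta / decomp.n_uncovered


def theta_uncertainty(
    n_covered: float,
    n_uncovered: float,
    sigma_n_covered: float,
    sigma_n_uncovered: float,
    source: SourceSpec,
) -> float:
    """1-sigma uncertainty of theta by the exact-differential method.

    With ``theta = (N_U - N_C) / ((1 - t) N_U)``, treating N_C and N_U as
    independent:

        sigma_theta^2 = (sigma_NC / ((1-t) N_U))^2
                      + (N_C * sigma_NU / ((1-t) N_U^2))^2
    """
    t = source.beta_transmission
    d_nc = sigma_n_covered / ((1.0 - t) * n_uncovered)
    d_nu = n_covered * sigma_n_uncovered / ((1.0 - t) * n_uncovered**2)
    return math.hypot(d_nc, d_nu)


def decompose(n_uncovered: float, theta: float) -> CountDecomposition:
    """Split uncovered counts by a known beta fraction theta."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    if n_uncovered < 0:
        raise ValueError("n_uncovered must be nonnegative")
    n_beta = n_uncovered * theta
    n_gamma = n_uncovered - n_beta
    return CountDecomposition(n_gamma=n_gamma, n_beta=n_beta, n_uncovered=n_uncovered)


def propagate_uncertainty(
    n_uncovered: float,
    sigma_n: float,
    theta: float,
    sigma_theta: float,
    k: float,
    sigma_k: float,
    component: "Component | str",
) -> float:
    """2-sigma dose uncertainty by first-order (exact-differential) combination.

    For the beta component, ``D = N_U * theta * k`` gives

        sigma_D^2 = (theta k sigma_N)^2 + (N_U k sigma_theta)^2
                  + (N_U theta sigma_k)^2

    and analogously with ``(1 - theta)`` for gamma (the theta-derivative term
    keeps magnitude ``N_U k sigma_theta`` for both components).  The value is
    returned doubled (k = 2 reporting convention).
    """
    if min(sigma_n, sigma_theta, sigma_k) < 0:
        raise ValueError("all sigmas must be nonnegative")
    g = theta if Component(component) is Component.BETA else 1.0 - theta
    var = (
        (g * k * sigma_n) ** 2
        + (n_uncovered * k * sigma_theta) ** 2
        + (n_uncovered * g * sigma_k) ** 2
    )
    return 2.0 * math.sqrt(var)


def _k_value(k: "CalibrationFactor | float") -> tuple[float, float]:
    if isinstance(k, CalibrationFactor):
        return k.k_hat, k.sd
    return float(k), 0.0


def classical_doses(
    n_uncovered: float,
    theta: float,
    k_gamma: "CalibrationFactor | float",
    k_beta: "CalibrationFactor | float",
    *,
    sigma_n: float = 0.0,
    sigma_theta: float = 0.0,
) -> tuple[DoseEstimate, DoseEstimate]:
    """Component doses from uncovered counts and the beta fraction theta.

        D_gamma = N_U (1 - theta) k_gamma
        D_beta  = N_U theta k_beta

    ``k_gamma``/``k_beta`` may be :class:`~tldose.core.CalibrationFactor`
    objects (their spreads enter the uncertainty) or bare floats (spread 0).

    Returns
    -------
    (gamma, beta)
        Two :class:`~tldose.core.DoseEstimate` objects with 2-sigma
        uncertainties from :func:`propagate_uncertainty`.
    """
    decomp = decompose(n_uncovered, theta)  # validates theta, n_uncovered
    kg, sg = _k_value(k_gamma)
    kb, sb = _k_value(k_beta)
    if kg <= 0 or kb <= 0:
        raise ValueError("calibration factors must be positive")
    d_gamma = decomp.n_gamma * kg
    d_beta = decomp.n_beta * kb
    u_gamma = propagate_uncertainty(
        n_uncovered, sigma_n, theta, sigma_theta, kg, sg, Component.GAMMA
    )
    u_beta = propagate_uncertainty(
        n_uncovered, sigma_n, theta, sigma_theta, kb, sb, Component.BETA
    )
    return (
        DoseEstimate(d_gamma, u_gamma, Component.GAMMA, "classical"),
        DoseEstimate(d_beta, u_beta, Component.BETA, "classical"),
    )
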