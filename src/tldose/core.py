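"""Domain types and basic estimation for two-pellet thermoluminescent dosimetry.

A personal dosimeter card carries TL pellets in a *covered* position (behind a
1 mm aluminium filter, which passes all gamma but only a fraction ``t`` of the
beta signal) and an *uncovered* position.  The dose-proportional observable is
the background-corrected integral of the heat-phase TL signal ("counts").
This module provides:

* the record types shared by every engine (readouts, calibration factors,
  dose estimates, Gaussian fit summaries);
* background correction;
* Gaussian fitting of pellet-batch count histograms with the coefficient of
  determination used as a shape-acceptance criterion (R^2 >= 0.85);
* calibration-factor estimation ``k = D / N`` from a batch irradiated with a
  known dose, with first-order (exact-differential) uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidBatchError,
    InvalidReadoutError,
)

__all__ = [
    "Position",
    "Component",
    "PelletReadout",
    "GaussianModel",
    "CalibrationFactor",
    "SourceSpec",
    "DoseEstimate",
    "R2_ACCEPT",
    "subtract_background",
    "fit_gaussian",
    "estimate_calibration_factor",
]

#: Minimum coefficient of determination for accepting a Gaussian shape.
R2_ACCEPT = 0.85

#: Valid method tags for a :class:`DoseEstimate`.
METHODS = frozenset(
    {
        "classical",
        "bayes-opt1",
        "bayes-opt2",
        "bayes-opt3",
        "mc-opt1",
        "mc-opt2",
        "mc-opt3",
    }
)


class Position(str, Enum):
    """Pellet position on the dosimeter card."""

    COVERED = "covered"
    UNCOVERED = "uncovered"


class Component(str, Enum):
    """Radiation field component."""

    BETA = "beta"
    GAMMA = "gamma"


def _as_component(component: "Component | str") -> Component:
    return Component(component)


@dataclass(frozen=True)
class PelletReadout:
    """One pellet's heat-phase count integral plus its shielding position.

    Parameters
    ----------
    counts
        Heat-phase count integral (counts, >= 0).
    position
        ``covered`` or ``uncovered``.
    background
        Background counts to subtract; defaults to 0 because bundled
        validation counts are already background-reduced.
    """

    counts: float
    position: Position
    background: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.counts) and self.counts >= 0):
            raise InvalidReadoutError(f"counts must be finite and >= 0, got {self.counts}")
        if not (math.isfinite(self.background) and self.background >= 0):
            raise InvalidReadoutError(
                f"background must be finite and >= 0, got {self.background}"
            )
        object.__setattr__(self, "position", Position(self.position))

    @property
    def corrected(self) -> float:
        """Background-corrected counts (see :func:`subtract_background`)."""
        return subtract_background(self)


@dataclass(frozen=True)
class GaussianModel:
    """Summary of a Gaussian fit to a count (or CF) frequency distribution."""

    mean: float
    sd: float
    r_squared: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")

    @property
    def passes(self) -> bool:
        """True when the fit meets the shape-acceptance criterion R^2 >= 0.85."""
        return self.r_squared >= R2_ACCEPT


@dataclass(frozen=True)
class CalibrationFactor:
    """Counts-to-dose conversion factor ``k`` (mSv per count) with its 1-sigma spread.

    The spread is the batch spread (not the standard error of the mean); it is
    what feeds the Gaussian prior ``p(k)`` of the Bayesian engine.
    """

    k_hat: float
    sd: float = 0.0
    source: str = ""
    position: Position = Position.UNCOVERED
    component: Component = Component.GAMMA

    def __post_init__(self) -> None:
        if not self.k_hat > 0:
            raise ValueError(f"k_hat must be positive, got {self.k_hat}")
        if not self.sd >= 0:
            raise ValueError(f"sd must be nonnegative, got {self.sd}")
        object.__setattr__(self, "position", Position(self.position))
        object.__setattr__(self, "component", Component(self.component))


@dataclass(frozen=True)
class SourceSpec:
    """A beta source and the fraction of its beta counts passing the covered filter.

    For a 90Sr/90Y source behind 1 mm of aluminium the transmitted beta
    fraction is 0.25.
    """

    name: str = "Sr-90/Y-90"
    beta_transmission: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta_transmission <= 1.0:
            raise ValueError(
                f"beta_transmission must be in [0, 1], got {self.beta_transmission}"
            )


@dataclass(frozen=True)
class DoseEstimate:
    """A component dose in mSv with its expanded (k = 2, i.e. 2-sigma) uncertainty."""

    value: float
    uncertainty_2sigma: float
    component: Component
    method: str

    def __post_init__(self) -> None:
        if not self.value >= 0:
            raise ValueError(f"dose must be nonnegative, got {self.value}")
        if not self.uncertainty_2sigma >= 0:
            raise ValueError(
                f"uncertainty must be nonnegative, got {self.uncertainty_2sigma}"
            )
        object.__setattr__(self, "component", Component(self.component))
        if self.method not in METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")

    def rounded(self, ndigits: int = 3) -> "tuple[float, float]":
        """Reporting convention: dose and 2-sigma uncertainty in mSv, 3 decimals."""
        return round(self.value, ndigits), round(self.uncertainty_2sigma, ndigits)


def subtract_background(readout: PelletReadout) -> float:
    """Return the background-corrected counts of a readout.

    Raises
    ------
    InvalidReadoutError
        If the background exceeds the recorded counts (a negative corrected
        signal is reported, never silently clamped).
    """
    corrected = readout.counts - readout.background
    if corrected < 0:
        raise InvalidReadoutError(
            f"background {readout.background} exceeds counts {readout.counts}"
        )
    return corrected


def fit_gaussian(samples: Sequence[float], n_bins: int = 20) -> GaussianModel:
    """Fit a Gaussian to a sample's binned frequency distribution.

    The model is parameterised by the sample mean and standard deviation
    (no free-parameter optimisation); the quality of the Gaussian shape is
    quantified by the coefficient of determination between the observed
    relative frequencies per bin and the Gaussian probability mass integrated
    over each bin,

        R^2 = 1 - SS_res / SS_tot,

    clipped to [0, 1].  A fit with ``r_squared >= 0.85`` passes the
    shape-acceptance criterion.

    Parameters
    ----------
    samples
        At least 10 real values with nonzero variance.
    n_bins
        Number of equal-width histogram bins (>= 5, default 20).

    Raises
    ------
    InsufficientDataError
        For fewer than 10 samples or zero sample variance.
    """
    if n_bins < 5:
        raise ValueError(f"n_bins must be >= 5, got {n_bins}")
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise InsufficientDataError(f"need at least 10 samples, got {x.size}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise InsufficientDataError("zero sample variance: nothing to fit")
    counts, edges = np.histogram(x, bins=n_bins)
    observed = counts / x.size
    model = np.diff(stats.norm.cdf(edges, loc=mean, scale=sd))
    ss_res = float(np.sum((observed - model) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return GaussianModel(mean=mean, sd=sd, r_squared=float(np.clip(r2, 0.0, 1.0)))


def estimate_calibration_factor(
    batch_counts: Sequence[float],
    delivered_dose: float,
    *,
    source: str = "",
    position: "Position | str" = Position.UNCOVERED,
    component: "Component | str" = Component.GAMMA,
) -> CalibrationFactor:
    """Estimate ``k = D / mean(N)`` from a pellet batch irradiated with a known dose.

    The spread is propagated from the batch count spread by the exact
    differential of ``k = D / N``:

        sd_k = D * sd_N / mean_N**2

    where ``sd_N`` is the batch standard deviation (ddof=1), so that the
    resulting spread can be used directly as the width of the Gaussian
    prior ``p(k)``.

    Raises
    ------
    InvalidBatchError
        If the batch is empty or contains a nonpositive count.
    """
    n = np.asarray(batch_counts, dtype=float)
    if n.size == 0:
        raise InvalidBatchError("empty calibration batch")
    if np.any(n <= 0):
        raise InvalidBatchError("calibration batch contains nonpositive counts")
    if not delivered_dose > 0:
        raise ValueError(f"delivered_dose must be positive, got {delivered_dose}")
    mean_n = float(n.mean())
    sd_n = float(n.std(ddof=1)) if n.size > 1 else 0.0
    k_hat = delivered_dose / mean_n
    sd_k = delivered_dose * sd_n / mean_n**2
    return CalibrationFactor(
        k_hat=k_hat,
        sd=sd_k,
        source=source,
        position=Position(position),
        component=Component(component),
    )
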