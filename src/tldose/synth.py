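"""Synthetic pellet batches and mixed-field exposures.

Real TL pellet batches respond to a uniform delivered dose with an
approximately Gaussian count distribution whose spread (a few percent CV)
reflects pellet-to-pellet sensitivity variation — much wider than Poisson
counting statistics at ~10^6 reader counts, because the counts are
reader-scaled rather than raw quanta.  The generator therefore uses
multiplicative Gaussian noise parameterised by a coefficient of variation.

It produces:

* calibration batches (default 150 pellets exposed to 1 mSv), for exercising
  the Gaussian fit and calibration-factor estimation;
* mixed-field exposures: covered/uncovered count pairs from chosen component
  doses run forward through the calibration map, for end-to-end parameter
  recovery of every assessment engine;
* virtual calibration campaigns for sources with assumed response parameters,
  written in the standard calibration CSV format and flagged ``virtual``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CalibrationFactor,
    Component,
    PelletReadout,
    Position,
    SourceSpec,
    estimate_calibration_factor,
)
from .errors import ConfigError

__all__ = [
    "BatchSpec",
    "ExposureSpec",
    "VirtualSourceSpec",
    "simulate_batch",
    "simulate_exposure",
    "simulate_exposure_readouts",
    "virtual_source_campaign",
]

#: Largest tolerated probability mass at nonpositive counts.
_MAX_NONPOSITIVE_MASS = 1e-3


@dataclass(frozen=True)
class BatchSpec:
    """A virtual calibration batch: n_pellets exposed to a common dose.

    Counts are Gaussian with mean ``mean_counts * true_dose / 1 mSv`` and
    relative spread ``cv`` (pellet sensitivity variation).
    """

    mean_counts: float
    cv: float
    n_pellets: int = 150
    true_dose: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_counts > 0:
            raise ConfigError(f"mean_counts must be positive, got {self.mean_counts}")
        if not 0.0 <= self.cv < 0.5:
            raise ConfigError(f"cv must be in [0, 0.5), got {self.cv}")
        if self.cv > 0 and stats.norm.cdf(-1.0 / self.cv) > _MAX_NONPOSITIVE_MASS:
            raise ConfigError(
                f"cv = {self.cv} puts more than {_MAX_NONPOSITIVE_MASS:.1%} of the "
                "count distribution at nonpositive values"
            )
        if not self.n_pellets >= 2:
            raise ConfigError(f"n_pellets must be >= 2, got {self.n_pellets}")
        if not self.true_dose > 0:
            raise ConfigError(f"true_dose must be positive, got {self.true_dose}")


def simulate_batch(spec: BatchSpec) -> np.ndarray:
    """Draw one batch of pellet counts (all positive; nonpositive draws are redrawn)."""
    rng = np.random.default_rng(spec.seed)
    mean = spec.mean_counts * spec.true_dose  # linear response, 1 mSv reference
    if spec.cv == 0.0:
        return np.full(spec.n_pellets, mean)
    out = rng.normal(mean, spec.cv * mean, size=spec.n_pellets)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, spec.cv * mean, size=int(bad.sum()))
        bad = out <= 0
    return out


def _k(value: "CalibrationFactor | float") -> float:
    return value.k_hat if isinstance(value, CalibrationFactor) else float(value)


@dataclass(frozen=True)
class ExposureSpec:
    """A mixed-field exposure of a two-pellet card batch.

    The noiseless mean counts follow the forward calibration map

        N_U = d_gamma / k_gamma + d_beta / k_beta
        N_C = d_gamma / k_gamma_covered + d_beta / k_beta_covered

    where the covered factors already embody the filter transmission (a
    measured covered-position beta factor is what a calibration campaign
    actually yields).  Each of the ``n_pellets`` pellets per position gets
    independent multiplicative Gaussian noise of relative spread
    ``noise_cv``; the exposure readout is the per-position batch mean,
    mirroring the averaged counts a card batch reports.
    """

    d_beta: float
    d_gamma: float
    source: SourceSpec
    k_gamma: "CalibrationFactor | float"
    k_beta: "CalibrationFactor | float"
    k_gamma_covered: "CalibrationFactor | float"
    k_beta_covered: "CalibrationFactor | float"
    noise_cv: float = 0.0
    n_pellets: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_beta < 0 or self.d_gamma < 0 or self.d_beta + self.d_gamma <= 0:
            raise ConfigError("component doses must be nonnegative with a positive total")
        if self.noise_cv < 0:
            raise ConfigError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.n_pellets < 1:
            raise ConfigError(f"n_pellets must be >= 1, got {self.n_pellets}")

    @property
    def mean_uncovered(self) -> float:
        return self.d_gamma / _k(self.k_gamma) + self.d_beta / _k(self.k_beta)

    @property
    def mean_covered(self) -> float:
        return self.d_gamma / _k(self.k_gamma_covered) + self.d_beta / _k(self.k_beta_covered)


def _noisy_counts(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.full(n, mean)
    out = rng.normal(mean, cv * mean, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, cv * mean, size=int(bad.sum()))
        bad = out <= 0
    return out


def simulate_exposure(spec: ExposureSpec) -> tuple[float, float]:
    """Simulate one exposure; returns mean corrected counts ``(n_covered, n_uncovered)``."""
    rng = np.random.default_rng(spec.seed)
    covered = _noisy_counts(rng, spec.mean_covered, spec.noise_cv, spec.n_pellets)
    uncovered = _noisy_counts(rng, spec.mean_uncovered, spec.noise_cv, spec.n_pellets)
    return float(covered.mean()), float(uncovered.mean())


def simulate_exposure_readouts(spec: ExposureSpec) -> list[PelletReadout]:
    """Per-pellet readouts of one exposure, for writing a readout CSV."""
    rng = np.random.default_rng(spec.seed)
    covered = _noisy_counts(rng, spec.mean_covered, spec.noise_cv, spec.n_pellets)
    uncovered = _noisy_counts(rng, spec.mean_uncovered, spec.noise_cv, spec.n_pellets)
    rows = [PelletReadout(float(c), Position.COVERED) for c in covered]
    rows += [PelletReadout(float(u), Position.UNCOVERED) for u in uncovered]
    return rows


@dataclass(frozen=True)
class VirtualSourceSpec:
    """Assumed response of a hypothetical source, for a virtual calibration campaign."""

    name: str
    component: Component
    position: Position
    batch: BatchSpec


def virtual_source_campaign(
    sources: Sequence[VirtualSourceSpec],
    path: "str | Path | None" = None,
) -> pd.DataFrame:
    """Run a virtual calibration campaign and return (optionally write) a
    calibration table.

    Each source's batch is simulated and reduced with
    :func:`~tldose.core.estimate_calibration_factor`; the output matches the
    standard calibration CSV format with an extra ``virtual`` flag column.
    """
    rows = []
    for src in sources:
        counts = simulate_batch(src.batch)
        cal = estimate_calibration_factor(
            counts,
            src.batch.true_dose,
            source=src.name,
            position=src.position,
            component=src.component,
        )
        rows.append(
            {
                "source": src.name,
                "component": Component(src.component).value,
                "position": Position(src.position).value,
                "k_hat": cal.k_hat,
                "sd_k": cal.sd,
                "virtual": True,
            }
        )
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, index=False)
    return table
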