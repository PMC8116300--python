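"""Monte Carlo dose assessment: a randomised iterative realisation of the
Bayesian model.

Each iteration draws the uncertain inputs from their Gaussian priors —
``theta`` (truncated to [0, 1]) and/or a calibration factor ``k`` (truncated
positive), per the option's knowledge state — optionally redraws the counts
``N ~ Normal(N_U, sigma_N)``, and pushes them through the classical dose map

    D_beta  = N * theta * k_beta
    D_gamma = N * (1 - theta) * k_gamma

The aggregated sample (default 100,000 iterations) is summarised as
mean +/- 2 sd.  Truncated-Gaussian draws use rejection sampling (acceptance
is essentially 100% for realistic spreads), so a fixed seed reproduces the
distribution bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .bayes import LikelihoodSpec, PosteriorGrid, PriorK, PriorTheta, posterior_mode
from .core import CalibrationFactor, Component, DoseEstimate
from .errors import ConfigError, TruncationBiasWarning

__all__ = [
    "McConfig",
    "DoseDistribution",
    "AgreementReport",
    "run_mc",
    "mc_vs_bayes_check",
]

#: Fraction of prior mass outside the truncation bounds that triggers a warning.
_TRUNCATION_WARN = 0.01


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo run settings.

    ``sigma_n_mode`` selects whether the counts are held at their measured
    value (``fixed-counts``) or redrawn each iteration from
    ``Normal(N_U, sigma_N)`` (``resampled-counts``); the latter makes the
    sample spread comparable with the Bayesian posterior width, which always
    includes the count likelihood.
    """

    option: int
    n_iter: int = 100_000
    seed: int = 0
    sigma_n_mode: str = "fixed-counts"

    def __post_init__(self) -> None:
        if self.option not in (1, 2, 3):
            raise ConfigError(f"option must be 1, 2 or 3, got {self.option}")
        if not self.n_iter >= 1:
            raise ConfigError(f"n_iter must be >= 1, got {self.n_iter}")
        if self.sigma_n_mode not in ("fixed-counts", "resampled-counts"):
            raise ConfigError(f"unknown sigma_n_mode {self.sigma_n_mode!r}")


@dataclass(frozen=True)
class DoseDistribution:
    """A Monte Carlo dose sample with its summary statistics."""

    samples: np.ndarray
    mean: float
    sd: float

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        scale = max(1.0, abs(self.mean))
        if abs(float(s.mean()) - self.mean) > 1e-12 * scale:
            raise ValueError("mean inconsistent with samples")
        sd = float(s.std(ddof=1)) if s.size > 1 else 0.0
        if abs(sd - self.sd) > 1e-12 * max(1.0, sd):
            raise ValueError("sd inconsistent with samples")

    @classmethod
    def from_samples(cls, samples: np.ndarray) -> "DoseDistribution":
        s = np.asarray(samples, dtype=float)
        sd = float(s.std(ddof=1)) if s.size > 1 else 0.0
        return cls(samples=s, mean=float(s.mean()), sd=sd)

    def estimate(self, component: "Component | str", option: int) -> DoseEstimate:
        """Summarise as mean +/- 2 sd."""
        return DoseEstimate(
            value=self.mean,
            uncertainty_2sigma=2.0 * self.sd,
            component=Component(component),
            method=f"mc-opt{option}",
        )


def _sample_truncated(
    rng: np.random.Generator,
    mu: float,
    sigma: float,
    lo: float,
    hi: float,
    n: int,
    label: str,
) -> np.ndarray:
    """Gaussian draws restricted to [lo, hi] by rejection."""
    outside = stats.norm.cdf(lo, mu, sigma) + stats.norm.sf(hi, mu, sigma)
    if outside > _TRUNCATION_WARN:
        warnings.warn(
            f"{outside:.1%} of the {label} prior mass lies outside [{lo:g}, {hi:g}]; "
            "truncated sampling will be biased relative to the untruncated Gaussian",
            TruncationBiasWarning,
            stacklevel=3,
        )
    out = rng.normal(mu, sigma, size=n)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def run_mc(
    config: McConfig,
    spec: LikelihoodSpec,
    theta: "PriorTheta | float",
    k: "PriorK | CalibrationFactor | float",
    component: "Component | str",
) -> DoseDistribution:
    """Run the Monte Carlo dose sampler for one component.

    The option fixes which inputs are sampled:

    ======  ==================  ==================
    option  theta               k
    ======  ==================  ==================
    1       sampled (PriorTheta)  fixed value
    2       fixed value           sampled (PriorK)
    3       sampled               sampled
    ======  ==================  ==================

    Passing a :class:`~tldose.core.CalibrationFactor` where a sampled k is
    required uses its spread as the prior sigma.
    """
    comp = Component(component)
    rng = np.random.default_rng(config.seed)
    n = config.n_iter

    if isinstance(k, CalibrationFactor):
        k = PriorK.from_calibration(k) if config.option in (2, 3) else k.k_hat

    sample_theta = config.option in (1, 3)
    sample_k = config.option in (2, 3)

    if sample_theta:
        if not isinstance(theta, PriorTheta):
            raise ConfigError(f"option {config.option} requires a PriorTheta, got {theta!r}")
        th = _sample_truncated(
            rng, theta.theta_hat, theta.sigma_theta, 0.0, 1.0, n, "theta"
        )
    else:
        if isinstance(theta, PriorTheta):
            raise ConfigError(f"option {config.option} requires a fixed theta value")
        th = np.full(n, float(theta))
        if not 0.0 <= float(theta) <= 1.0:
            raise ConfigError(f"theta must be in [0, 1], got {theta}")

    if sample_k:
        if not isinstance(k, PriorK):
            raise ConfigError(f"option {config.option} requires a PriorK, got {k!r}")
        kv = _sample_truncated(rng, k.k_hat, k.sigma_k, 0.0, np.inf, n, "k")
    else:
        if isinstance(k, PriorK):
            raise ConfigError(f"option {config.option} requires a fixed k value")
        kv = np.full(n, float(k))
        if not float(k) > 0:
            raise ConfigError(f"k must be positive, got {k}")

    if config.sigma_n_mode == "resampled-counts":
        counts = _sample_truncated(rng, spec.n_uncovered, spec.sigma_n, 0.0, np.inf, n, "N")
    else:
        counts = np.full(n, spec.n_uncovered)

    g = th if comp is Component.BETA else 1.0 - th
    return DoseDistribution.from_samples(counts * g * kv)


@dataclass(frozen=True)
class AgreementReport:
    """Cross-engine consistency between a Monte Carlo sample and a gridded posterior."""

    mean_gap: float
    sup_distance: float
    tolerance: float
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "passed", self.mean_gap < self.tolerance)


def mc_vs_bayes_check(dist: DoseDistribution, grid: PosteriorGrid) -> AgreementReport:
    """Compare a Monte Carlo dose sample against a gridded posterior.

    Reports the absolute gap between the MC mean and the posterior mode, and
    the Kolmogorov-Smirnov-style sup distance between the empirical CDF and
    the grid CDF.  The check passes when the mean gap is below
    ``3 sd / sqrt(n_iter)`` plus one grid step.
    """
    n = dist.samples.size
    mode = posterior_mode(grid)
    mean_gap = abs(dist.mean - mode)
    tol = 3.0 * dist.sd / np.sqrt(n) + grid.step
    x = np.sort(dist.samples)
    grid_cdf_at_x = np.interp(x, grid.dose_grid, grid.cdf())
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    sup = float(
        np.maximum(np.abs(ecdf_hi - grid_cdf_at_x), np.abs(ecdf_lo - grid_cdf_at_x)).max()
    )
    return AgreementReport(mean_gap=float(mean_gap), sup_distance=sup, tolerance=float(tol))
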