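"""Gridded Bayesian posterior inference of mixed-field component doses.

The measurement model treats the uncovered-pellet count integral as Gaussian,
``N ~ Normal(N_U, sigma_N)``.  A candidate component dose ``D`` implies a
count value through the calibration map,

    N(D) = D / ((1 - theta) k_gamma)   (gamma)
    N(D) = D / (theta k_beta)          (beta)

so the likelihood of a dose is the Gaussian count density evaluated at the
implied counts.  Prior knowledge enters as Gaussian distributions on the beta
count fraction ``theta`` and/or on a calibration factor ``k``; the three
supported knowledge states are

    option 1:  p(theta) Gaussian, k known          -> marginalise over theta
    option 2:  theta known, p(k) Gaussian          -> marginalise over k
    option 3:  both unknown                        -> marginalise over both

The (unnormalised) marginal posterior is tabulated on a uniform dose grid,
normalised by trapezoidal quadrature, and summarised by its mode (quadratic
interpolation around the grid maximum) and by the Cramer-Rao width

    sigma_D = 1 / sqrt(|d^2 ln P / dD^2|)  at the mode,

reported doubled (k = 2) as an approximate 95% highest-density interval.

Numerical scheme: all marginalisation integrals use trapezoidal quadrature on
uniform grids covering +/- 6 prior sigmas, truncated to theta in [0, 1] and
k > 0 (the truncated priors are renormalised).  Quadrature error on these
smooth, rapidly decaying integrands is far below the 0.001 mSv reporting
resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import CalibrationFactor, Component, DoseEstimate
from .errors import (
    DegenerateLikelihoodError,
    GridCoverageError,
    IllConditionedPosteriorError,
    MultimodalPosteriorWarning,
)

__all__ = [
    "LikelihoodSpec",
    "PriorTheta",
    "PriorK",
    "PosteriorGrid",
    "likelihood_density",
    "posterior_option1",
    "posterior_option2",
    "posterior_option3",
    "posterior_mode",
    "posterior_mean",
    "cramer_rao_sigma",
    "estimate_from_posterior",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)
_EDGE = 1e-12  # open-interval guard for theta


@dataclass(frozen=True)
class LikelihoodSpec:
    """Measured uncovered counts and their Gaussian spread sigma_N."""

    n_uncovered: float
    sigma_n: float

    def __post_init__(self) -> None:
        if not self.n_uncovered > 0:
            raise ValueError(f"n_uncovered must be positive, got {self.n_uncovered}")
        if not self.sigma_n > 0:
            raise ValueError(f"sigma_n must be positive, got {self.sigma_n}")


@dataclass(frozen=True)
class PriorTheta:
    """Gaussian prior on the beta count fraction, truncated to [0, 1]."""

    theta_hat: float
    sigma_theta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_hat < 1.0:
            raise ValueError(f"theta_hat must be in (0, 1), got {self.theta_hat}")
        if not self.sigma_theta > 0:
            raise ValueError(f"sigma_theta must be positive, got {self.sigma_theta}")


@dataclass(frozen=True)
class PriorK:
    """Gaussian prior on a calibration factor, truncated to k > 0."""

    k_hat: float
    sigma_k: float

    def __post_init__(self) -> None:
        if not self.k_hat > 0:
            raise ValueError(f"k_hat must be positive, got {self.k_hat}")
        if not self.sigma_k > 0:
            raise ValueError(f"sigma_k must be positive, got {self.sigma_k}")

    @classmethod
    def from_calibration(cls, cal: CalibrationFactor) -> "PriorK":
        return cls(k_hat=cal.k_hat, sigma_k=cal.sd)


@dataclass(frozen=True)
class PosteriorGrid:
    """A normalised posterior density of a component dose tabulated on a grid."""

    dose_grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.dose_grid, dtype=float)
        p = np.asarray(self.density, dtype=float)
        if x.ndim != 1 or x.shape != p.shape:
            raise ValueError("dose_grid and density must be matching 1-D arrays")
        if not np.all(np.diff(x) > 0):
            raise ValueError("dose_grid must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("density must be nonnegative")
        integral = float(np.trapezoid(p, x))
        if abs(integral - 1.0) > 1e-6:
            raise ValueError(f"density must integrate to 1 +/- 1e-6, got {integral}")
        object.__setattr__(self, "dose_grid", x)
        object.__setattr__(self, "density", p)

    @property
    def step(self) -> float:
        return float(self.dose_grid[1] - self.dose_grid[0])

    def cdf(self) -> np.ndarray:
        """Cumulative distribution on the grid (trapezoidal)."""
        from scipy.integrate import cumulative_trapezoid

        c = cumulative_trapezoid(self.density, self.dose_grid, initial=0.0)
        return c / c[-1]


def _g(component: "Component | str", theta: "float | np.ndarray") -> "float | np.ndarray":
    """Count-fraction factor of the dose map: theta for beta, 1 - theta for gamma."""
    if Component(component) is Component.BETA:
        return theta
    return 1.0 - theta


def likelihood_density(
    dose: "float | np.ndarray",
    component: "Component | str",
    theta: float,
    k: float,
    spec: LikelihoodSpec,
) -> "float | np.ndarray":
    """Gaussian count likelihood of a dose.

    Evaluates the Normal(N_U, sigma_N) density at the counts implied by
    ``dose``: ``dose / ((1-theta) k)`` for gamma, ``dose / (theta k)`` for
    beta.

    Raises
    ------
    DegenerateLikelihoodError
        At theta = 0 (beta) or theta = 1 (gamma), where the implied-count
        map divides by zero.
    """
    comp = Component(component)
    g = _g(comp, theta)
    if not k > 0:
        raise ValueError(f"k must be positive, got {k}")
    if g == 0.0:
        raise DegenerateLikelihoodError(
            f"theta = {theta} makes the {comp.value} dose-to-counts map singular"
        )
    implied = np.asarray(dose, dtype=float) / (g * k)
    z = (spec.n_uncovered - implied) / spec.sigma_n
    out = np.exp(-0.5 * z**2) / (spec.sigma_n * _SQRT2PI)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# prior and dose grids


def _theta_grid(prior: PriorTheta, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform theta grid over +/- 6 sigma truncated to [0, 1], with
    renormalised prior weights."""
    lo = max(_EDGE, prior.theta_hat - 6.0 * prior.sigma_theta)
    hi = min(1.0 - _EDGE, prior.theta_hat + 6.0 * prior.sigma_theta)
    grid = np.linspace(lo, hi, n)
    w = np.exp(-0.5 * ((grid - prior.theta_hat) / prior.sigma_theta) ** 2)
    w /= np.trapezoid(w, grid)
    return grid, w


def _k_grid(prior: PriorK, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform k grid over +/- 6 sigma truncated to k > 0, with renormalised
    prior weights."""
    lo = max(_EDGE * prior.k_hat, prior.k_hat - 6.0 * prior.sigma_k)
    hi = prior.k_hat + 6.0 * prior.sigma_k
    grid = np.linspace(lo, hi, n)
    w = np.exp(-0.5 * ((grid - prior.k_hat) / prior.sigma_k) ** 2)
    w /= np.trapezoid(w, grid)
    return grid, w


def default_dose_grid(spec: LikelihoodSpec, k_max: float, n_dose: int = 4096) -> np.ndarray:
    """Default uniform dose grid: [0, 2 N_U k_max]."""
    return np.linspace(0.0, 2.0 * spec.n_uncovered * k_max, n_dose)


def _finalize(
    dose: np.ndarray,
    unnorm: np.ndarray,
    expand: "callable | None",
) -> PosteriorGrid:
    """Normalise an unnormalised posterior; auto-expand the upper grid limit
    while boundary mass is non-negligible (only when the grid was defaulted)."""
    for _ in range(6):
        peak = float(unnorm.max())
        if peak <= 0.0 or not np.isfinite(peak):
            raise GridCoverageError("posterior mass not covered by the dose grid")
        if expand is None or unnorm[-1] <= 1e-9 * peak:
            break
        hi = dose[-1] * 1.5
        dose = np.linspace(dose[0], hi, dose.size)
        unnorm = expand(dose)
    else:
        raise GridCoverageError("dose grid auto-expansion did not converge")
    density = unnorm / np.trapezoid(unnorm, dose)
    return PosteriorGrid(dose_grid=dose, density=density)


# ---------------------------------------------------------------------------
# marginal posteriors


def posterior_option1(
    component: "Component | str",
    spec: LikelihoodSpec,
    prior_theta: PriorTheta,
    k: "CalibrationFactor | float",
    *,
    dose_grid: "np.ndarray | None" = None,
    n_theta: int = 512,
    n_dose: int = 4096,
) -> PosteriorGrid:
    """Marginal posterior with a Gaussian theta prior and a known k.

        P(D) ∝ ∫ L(D | theta) p(theta) dtheta,  theta in [0, 1]
    """
    comp = Component(component)
    k_val = k.k_hat if isinstance(k, CalibrationFactor) else float(k)
    if not k_val > 0:
        raise ValueError("k must be positive")
    tg, tw = _theta_grid(prior_theta, n_theta)
    g = np.asarray(_g(comp, tg))
    inv = 1.0 / (g * k_val)

    def compute(dose: np.ndarray) -> np.ndarray:
        z = (spec.n_uncovered - np.outer(dose, inv)) / spec.sigma_n
        integrand = np.exp(-0.5 * z**2) * tw
        return np.trapezoid(integrand, tg, axis=1) / (spec.sigma_n * _SQRT2PI)

    supplied = dose_grid is not None
    dose = np.asarray(dose_grid, float) if supplied else default_dose_grid(spec, k_val, n_dose)
    return _finalize(dose, compute(dose), None if supplied else compute)


def posterior_option2(
    component: "Component | str",
    spec: LikelihoodSpec,
    theta: float,
    prior_k: PriorK,
    *,
    dose_grid: "np.ndarray | None" = None,
    n_k: int = 512,
    n_dose: int = 4096,
) -> PosteriorGrid:
    """Marginal posterior with a known theta and a Gaussian k prior.

        P(D) ∝ ∫ L(D | k) p(k) dk,  k > 0
    """
    comp = Component(component)
    g = float(_g(comp, theta))
    if g <= 0.0:
        raise DegenerateLikelihoodError(
            f"theta = {theta} makes the {comp.value} dose-to-counts map singular"
        )
    kg, kw = _k_grid(prior_k, n_k)
    inv = 1.0 / (g * kg)

    def compute(dose: np.ndarray) -> np.ndarray:
        z = (spec.n_uncovered - np.outer(dose, inv)) / spec.sigma_n
        integrand = np.exp(-0.5 * z**2) * kw
        return np.trapezoid(integrand, kg, axis=1) / (spec.sigma_n * _SQRT2PI)

    k_max = prior_k.k_hat + 6.0 * prior_k.sigma_k
    supplied = dose_grid is not None
    dose = np.asarray(dose_grid, float) if supplied else default_dose_grid(spec, k_max, n_dose)
    return _finalize(dose, compute(dose), None if supplied else compute)


def posterior_option3(
    component: "Component | str",
    spec: LikelihoodSpec,
    prior_theta: PriorTheta,
    prior_k: PriorK,
    *,
    dose_grid: "np.ndarray | None" = None,
    n_theta: int = 512,
    n_k: int = 512,
    n_dose: int = 4096,
) -> PosteriorGrid:
    """Double-marginal posterior with Gaussian priors on both theta and k.

        P(D) ∝ ∫∫ L(D | k, theta) p(k) p(theta) dk dtheta

    Both marginalisations are trapezoidal.  Because theta enters the
    integrand only through the implied component counts ``c = D / g(theta)``,
    the inner k-marginal is tabulated once on a dense ``c`` grid (``n_c``
    nodes) and reused across the theta quadrature through a cubic spline;
    the spline reproduces the direct nested quadrature to ~1e-9 of the peak
    at a fraction of its cost.
    """
    comp = Component(component)
    tg, tw = _theta_grid(prior_theta, n_theta)
    kg, kw = _k_grid(prior_k, n_k)
    g = np.asarray(_g(comp, tg))
    n_c = 32768

    def compute(dose: np.ndarray) -> np.ndarray:
        from scipy.interpolate import CubicSpline

        c = np.linspace(0.0, dose[-1] / g.min(), n_c)
        z = (spec.n_uncovered - np.outer(c, 1.0 / kg)) / spec.sigma_n
        f_inner = np.trapezoid(np.exp(-0.5 * z**2) * kw, kg, axis=1)
        spline = CubicSpline(c, f_inner)
        vals = np.clip(spline(np.outer(dose, 1.0 / g)), 0.0, None)
        out = np.trapezoid(vals * tw, tg, axis=1)
        return out / (spec.sigma_n * _SQRT2PI)

    k_max = prior_k.k_hat + 6.0 * prior_k.sigma_k
    supplied = dose_grid is not None
    dose = np.asarray(dose_grid, float) if supplied else default_dose_grid(spec, k_max, n_dose)
    return _finalize(dose, compute(dose), None if supplied else compute)


# ---------------------------------------------------------------------------
# posterior summaries


def _argmax_checked(grid: PosteriorGrid) -> int:
    p = grid.density
    m = int(np.argmax(p))
    if m == 0 or m == p.size - 1:
        raise GridCoverageError("posterior maximum lies on a grid boundary")
    interior = p[1:-1]
    local_max = (interior > p[:-2]) & (interior >= p[2:]) & (interior > 1e-9 * p[m])
    if int(local_max.sum()) > 1:
        warnings.warn(
            "posterior density is multimodal; returning the global maximum",
            MultimodalPosteriorWarning,
            stacklevel=3,
        )
    return m


def posterior_mode(grid: PosteriorGrid) -> float:
    """Dose at the posterior maximum, refined by quadratic interpolation
    through the three grid points around the maximum."""
    m = _argmax_checked(grid)
    x = grid.dose_grid
    y = grid.density
    denom = y[m - 1] - 2.0 * y[m] + y[m + 1]
    if denom == 0.0:
        return float(x[m])
    shift = 0.5 * (y[m - 1] - y[m + 1]) / denom
    return float(x[m] + shift * (x[m + 1] - x[m]))


def posterior_mean(grid: PosteriorGrid) -> float:
    """Posterior mean dose (trapezoidal)."""
    return float(np.trapezoid(grid.dose_grid * grid.density, grid.dose_grid))


def cramer_rao_sigma(grid: PosteriorGrid) -> float:
    """Cramer-Rao width of the posterior: 1 / sqrt(|d^2 ln P / dD^2|) at the mode.

    The second derivative of the log-density is taken by central finite
    differences on the grid.  The reporting layer doubles this value
    (k = 2, approximate 95% HDI).

    Raises
    ------
    IllConditionedPosteriorError
        If the log-density curvature at the mode is not negative.
    """
    m = _argmax_checked(grid)
    p = grid.density
    if p[m - 1] <= 0.0 or p[m + 1] <= 0.0:
        raise IllConditionedPosteriorError("density not strictly positive around the mode")
    h = grid.dose_grid[m + 1] - grid.dose_grid[m]
    d2 = (math.log(p[m - 1]) - 2.0 * math.log(p[m]) + math.log(p[m + 1])) / h**2
    if d2 >= 0.0:
        raise IllConditionedPosteriorError(
            f"nonnegative log-density curvature at the mode ({d2})"
        )
    return 1.0 / math.sqrt(-d2)


def estimate_from_posterior(
    grid: PosteriorGrid, component: "Component | str", option: int
) -> DoseEstimate:
    """Summarise a posterior as a dose estimate: mode +/- doubled Cramer-Rao width."""
    if option not in (1, 2, 3):
        raise ValueError(f"option must be 1, 2 or 3, got {option}")
    return DoseEstimate(
        value=posterior_mode(grid),
        uncertainty_2sigma=2.0 * cramer_rao_sigma(grid),
        component=Component(component),
        method=f"bayes-opt{option}",
    )
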