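"""Exception and warning hierarchy for the toolkit.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class TldoseError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(TldoseError):
    """Invalid configuration: unknown keys, inconsistent method/option combos."""


class DataError(TldoseError):
    """Invalid or insufficient input data."""


class InvalidReadoutError(DataError):
    """Background exceeds the recorded counts."""


class InsufficientDataError(DataError):
    """Too few samples, or zero variance, for a distribution fit."""


class InvalidBatchError(DataError):
    """A calibration batch contains nonpositive counts or is empty."""


class NegativeBetaError(DataError):
    """Covered counts exceed uncovered counts: the implied beta signal is negative."""


class NegativeGammaError(DataError):
    """The implied gamma signal is negative (beam inconsistent with the filter transmission)."""


class UndefinedThetaError(DataError):
    """The beta count fraction is undefined for zero uncovered counts."""


class DegenerateLikelihoodError(DataError):
    """The dose-to-counts map divides by zero (theta = 0 for beta, theta = 1 for gamma)."""


class GridCoverageError(TldoseError):
    """The dose grid misses the posterior mass, or the mode sits on a grid boundary."""


class IllConditionedPosteriorError(TldoseError):
    """Nonnegative log-density curvature at the mode: no Cramer-Rao width exists."""


class TruncationBiasWarning(UserWarning):
    """More than 1% of a sampling prior's mass lies outside its truncation bounds."""


class MultimodalPosteriorWarning(UserWarning):
    """The tabulated posterior has more than one local maximum."""


class ClampedBetaWarning(UserWarning):
    """A small negative beta count was clamped to zero."""
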