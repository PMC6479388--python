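"""Exception hierarchy for pbpkit.

All pbpkit errors derive from :class:`PBPKitError` so callers can catch the
package's failures with a single except clause while still letting genuine
programming errors (TypeError etc.) propagate.
"""


class PBPKitError(Exception):
    """Base class for all pbpkit errors."""


class UnsupportedSpeciesError(PBPKitError, KeyError):
    """Requested species has no built-in physiology."""


class InsufficientPointsError(PBPKitError, ValueError):
    """Too few (distinct) data points for the requested regression."""


class InvalidWeightError(PBPKitError, ValueError):
    """A 1/x^2 weighting was requested for a non-positive concentration."""


class NonInvertibleResponseError(PBPKitError, ValueError):
    """Calibration response has no real inverse concentration."""


class LogDomainError(PBPKitError, ValueError):
    """Logarithm requested of a non-positive observation."""


class DomainError(PBPKitError, ValueError):
    """Input outside the mathematical domain of an operation."""


class NoDataError(PBPKitError, ValueError):
    """An operation received an empty data set."""


class SolverFailureError(PBPKitError, RuntimeError):
    """ODE integration failed or produced a non-finite state."""


class CalibrationFailureError(PBPKitError, RuntimeError):
    """Model calibration could not evaluate or converge."""


class ConfigurationError(PBPKitError, ValueError):
    """Missing or inconsistent configuration input."""


class SchemaError(PBPKitError, ValueError):
    """An input table does not match the expected column schema."""
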