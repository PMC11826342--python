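"""Exception hierarchy for the analysis pipeline.

Every stage raises a subclass of :class:`CalumenError` so the cohort driver
can catch failures per cell, log the reason and continue.
"""


class CalumenError(Exception):
    """Base class for all package errors."""


class CalibrationEpochAbsentError(CalumenError):
    """A required Fmax/Fmin calibration epoch is missing from the trace."""


class DegenerateCalibrationError(CalumenError):
    """Estimated Fmax is not above Fmin; the sensor record is unusable."""


class InvalidCalibrationError(CalumenError):
    """Sensor parameters violate their invariants."""


class DomainError(CalumenError, ValueError):
    """Input outside the physical domain (e.g. negative concentration)."""


class NoUptakeError(CalumenError):
    """No refill detected after store depletion (e.g. pump inhibited)."""


class InsufficientDataError(CalumenError):
    """Too few samples to perform the requested operation."""


class InsufficientHighLoadError(InsufficientDataError):
    """Too few points above the high-load threshold for the back-pressure fit."""


class InsufficientSpanError(InsufficientDataError):
    """Activation points do not span a wide enough load range."""


class DegenerateFitError(CalumenError):
    """A fit converged to a physically meaningless parameter set."""


class FitFailureError(CalumenError):
    """Nonlinear fit failed to converge; diagnostics in ``args``."""


class EmptyCohortError(CalumenError):
    """Every cell in the cohort was excluded; nothing to report."""


class InsufficientGroupError(CalumenError):
    """A group comparison needs at least two cells per group."""


class StabilityError(CalumenError):
    """Forward integration step exceeded the stability bound; lower dt_sim."""
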