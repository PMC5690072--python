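"""Exception and warning types shared across the package."""


class DriftTrackError(Exception):
    """Base class for all drifttrack errors."""


class ValidationError(DriftTrackError, ValueError):
    """Invalid input data, configuration, or domain-object invariant violation."""


class ParseError(ValidationError):
    """A log file could not be parsed into a valid Session."""


class SingularFitError(DriftTrackError):
    """The least-squares design for a (marker, axis) fit is rank deficient."""


class EstimationError(DriftTrackError):
    """A drift/baseline estimate could not be formed (e.g. missing peaks)."""


class DriftRateWarning(UserWarning):
    """Residual trend in the correction-training window suggests ongoing drift.

    Emitted when the baseline appears to still be moving while the intercept
    correction is being estimated; the correction may not hold during delivery.
    """
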