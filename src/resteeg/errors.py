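"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`ResteegError`, so callers can distinguish domain failures
(bad files, too-short recordings, degenerate statistics) from bugs.
"""


class ResteegError(Exception):
    """Base class for all errors raised by resteeg."""


class FormatError(ResteegError):
    """A file could not be parsed in the named format."""


class MontageError(ResteegError):
    """Channel labels could not be reconciled with the montage."""


class ParameterError(ResteegError):
    """An analysis parameter is out of its valid range."""


class InsufficientDataError(ResteegError):
    """A recording (or cohort) is too short/small for the requested analysis."""


class CalibrationError(ResteegError):
    """Artifact-subspace calibration could not be performed."""


class ModelError(ResteegError):
    """A fitted model was applied to incompatible data."""


class ReferenceError_(ResteegError):
    """Re-referencing is undefined (fewer than two channels)."""


class EstimationError(ResteegError):
    """A spectral estimate is undefined for the given segmentation."""


class UndefinedCorrelationError(ResteegError):
    """Pearson correlation undefined (zero variance or n < 3)."""


class PairingError(ResteegError):
    """Two tables/logs that must align (by subject, item, condition) do not."""


class ConfigurationError(ResteegError):
    """A configuration object is internally inconsistent."""
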