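"""Exception hierarchy shared by all qappg modules."""


class QappgError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QappgError):
    """Invalid or missing configuration (bad sample rate, unknown algorithm id, ...)."""


class ParseError(QappgError):
    """A data file could not be parsed; the message names the offending row."""


class ContractError(QappgError):
    """A caller violated an operation precondition (length mismatch, missing bypass, ...)."""


class DegenerateInputError(QappgError):
    """Input is structurally valid but unusable (constant segment, too short for a filter)."""


class ReferenceUnavailableError(QappgError):
    """No reference heart rate could be derived for a segment (e.g. < 2 R peaks)."""


class DegenerateTrainingError(QappgError):
    """A classifier stage cannot be trained (single-class labels)."""


class CalibrationError(QappgError):
    """Reject-rate calibration could not reach the requested target."""


class UndefinedMetricsError(QappgError):
    """Metrics requested over an empty retained set."""
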