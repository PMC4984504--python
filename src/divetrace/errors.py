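"""Exception hierarchy for divetrace."""


class DivetraceError(Exception):
    """Base class for all divetrace errors."""


class TagFormatError(DivetraceError):
    """Input file cannot be mapped to the expected tag columns."""


class TagValidationError(DivetraceError):
    """Parsed records violate a series invariant (e.g. non-monotone time)."""


class AnnotationError(DivetraceError):
    """An environmental annotation could not be resolved (e.g. oxygen
    profile does not cover the excursion's depth range)."""


class DegenerateDataError(DivetraceError):
    """Data carry no usable variation for the requested operation
    (identical profiles, zero depth range, zero variance)."""


class InsufficientRecordsError(DivetraceError):
    """Too few records to identify the requested model."""


class ConfigError(DivetraceError):
    """Invalid simulation or pipeline configuration."""
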