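"""Exception hierarchy for tremor-recording analysis."""


class TremorError(Exception):
    """Base class for all package errors."""


class FormatError(TremorError):
    """A file does not conform to the expected delimited-text layout."""


class DataError(TremorError):
    """Input data violate a precondition (non-finite samples, too short, ...)."""


class ConfigurationError(TremorError):
    """Missing or inconsistent configuration (sampling rate, filter corners, ...)."""


class BoundsError(TremorError):
    """A requested segment lies outside the recording."""


class UnitError(TremorError):
    """Incompatible kinematic units (acceleration vs velocity)."""
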