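"""Exception hierarchy for dimertrack."""


class DimertrackError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DimertrackError):
    """A simulation or run configuration violates an invariant."""


class SchemaError(DimertrackError):
    """A table is missing required columns or contains invalid values."""


class ParseError(DimertrackError):
    """A file could not be parsed; the message carries the offending row."""


class FormatError(DimertrackError):
    """An image stack or other binary artifact is malformed."""


class IdentifiabilityError(DimertrackError):
    """Too few or degenerate data to estimate a transform."""


class AnalysisError(DimertrackError):
    """An analysis precondition is not met (e.g. empty sample)."""
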