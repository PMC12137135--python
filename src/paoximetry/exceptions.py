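"""Exception hierarchy for the paoximetry pipeline."""


class PaoximetryError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PaoximetryError):
    """A required configuration entry (e.g. an extinction row) is missing."""


class ValidationError(PaoximetryError):
    """An input violates a documented invariant."""


class GeometryError(PaoximetryError):
    """An image is too small for the requested spatial operation."""


class NormalizationError(PaoximetryError):
    """The pre-irradiation baseline is empty or non-positive."""


class StatisticsError(PaoximetryError):
    """A statistical routine received a degenerate sample."""


class StabilityError(PaoximetryError):
    """The phantom integration step is too large for the rate constants."""
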