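"""Exception types raised across the package."""


class ArdkitError(Exception):
    """Base class for all ardkit errors."""


class AgeGridError(ArdkitError):
    """Input does not cover exactly the integer ages 21..84."""


class InvalidFamilyError(ArdkitError):
    """A synthetic curve family's hazard leaves the valid [0, 1) range."""


class StandardisationError(ArdkitError):
    """A curve cannot be standardised (all rates zero)."""


class UndefinedMedianError(ArdkitError):
    """Median onset age requested for a disease with zero total cases."""


class InsufficientDataError(ArdkitError):
    """Too few positive-rate ages to fit a log-scale onset model."""


class FitError(ArdkitError):
    """A regression fit failed (e.g. rank-deficient design)."""


class MissingMetadataError(ArdkitError):
    """A clustered disease has no metadata row."""
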