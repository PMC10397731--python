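"""Exception hierarchy shared across the package."""


class RhythmCodeError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(RhythmCodeError, ValueError):
    """Raised when input data violates a precondition (non-finite, too short, ...)."""


class InvalidSpecError(RhythmCodeError, ValueError):
    """Raised when a smoothing/classifier specification is malformed."""


class ConfigError(RhythmCodeError, ValueError):
    """Raised when a configuration value is inconsistent or unusable."""


class TooShortSequenceError(InvalidInputError):
    """Raised when a rhythm sequence is too short for windowed code extraction."""


class TooFewTrialsError(InvalidInputError):
    """Raised when a cross-validation design has fewer than three trials."""


class IncompleteEvaluationError(RhythmCodeError, ValueError):
    """Raised when a selection step is missing accuracy records it requires."""


class UnmappedChannelError(RhythmCodeError, KeyError):
    """Raised when a channel name cannot be assigned to a scalp region."""
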