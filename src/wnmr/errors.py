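"""Exception types shared across the package.

All are ValueError subclasses so callers that do not care about the
distinction can catch a single base class.
"""


class WnmrError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(WnmrError):
    """File structure is not one of the supported dialects."""


class ParseError(WnmrError):
    """A cell failed to parse; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class InsufficientDataError(WnmrError):
    """Too few points/rows for the requested operation."""


class IntegrityError(WnmrError):
    """Inconsistent study bookkeeping (duplicate codes, mismatched labs...)."""


class VocabularyError(WnmrError):
    """A label outside the controlled vocabulary."""


class DomainError(WnmrError):
    """A numeric argument outside the mathematical domain of an operation."""


class ConfigurationError(WnmrError):
    """Missing or contradictory configuration."""


class FlatSignalError(WnmrError):
    """Signal carries no resolvable decay above the noise floor."""
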