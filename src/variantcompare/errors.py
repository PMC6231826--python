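"""Exception hierarchy.

All data-level failures derive from :class:`VariantCompareError` so callers
(and the CLI) can distinguish bad data (exit 1) from bad arguments (exit 2).
"""


class VariantCompareError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(VariantCompareError):
    """A malformed line in a raw genotype file.

    Carries the 1-based line number where parsing failed.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class DuplicateRecordError(VariantCompareError):
    """A duplicate key (rsid, or (rsid, risk_allele)) within one container."""


class ValidationError(VariantCompareError):
    """A field value outside its documented domain."""


class FormatError(VariantCompareError):
    """A CSV/JSON document that does not match the expected schema."""


class ArityError(VariantCompareError):
    """Wrong number of persons for an operation (comparisons take 2-4)."""


class IdentityError(VariantCompareError):
    """An unknown or duplicated person identifier."""


class ConfigError(VariantCompareError):
    """An invalid simulation or runtime configuration."""
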