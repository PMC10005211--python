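"""Exception hierarchy shared by all pipeline stages."""


class NutrimendelError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NutrimendelError):
    """A required column, key or setting is missing or malformed."""


class ParseError(NutrimendelError):
    """A data row could not be converted; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class ValidationError(NutrimendelError):
    """A record or record set violates a domain invariant."""


class HarmonizationError(NutrimendelError):
    """Exposure and outcome alleles cannot be reconciled for a SNP."""


class PalindromicSNPError(HarmonizationError):
    """A/T or C/G SNP whose strand cannot be resolved from allele codes."""


class CollinearityError(NutrimendelError):
    """The multi-exposure design matrix is rank deficient."""


class DomainError(NutrimendelError):
    """A numeric argument is outside the mathematically valid domain."""
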