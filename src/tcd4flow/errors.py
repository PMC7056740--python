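"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError -> 2, FormatError -> 3,
NumericalError -> 4.
"""


class TCD4Error(Exception):
    """Base class for all package errors."""


class ValidationError(TCD4Error):
    """Invalid arguments, configuration, or sample state."""


class ConfigurationError(ValidationError):
    """Inconsistent configuration (missing markers, mismatched taxonomy...)."""


class FormatError(TCD4Error):
    """Malformed or unsupported file content."""


class UnsupportedDialectError(FormatError):
    """FCS dialect outside the supported envelope ($MODE, $DATATYPE...)."""


class NumericalError(TCD4Error):
    """Numerical failure (singular spillover, zero variance...)."""
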