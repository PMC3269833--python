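"""Exception hierarchy for switchscan.

All anticipated user-facing failures derive from :class:`SwitchScanError`
so the CLI can map them to exit code 1; programming errors propagate.
"""


class SwitchScanError(Exception):
    """Base class for all switchscan errors."""


class ValidationError(SwitchScanError, ValueError):
    """Invalid parameter, configuration, or malformed input table."""


class InsufficientDataError(ValidationError):
    """Too few observations to fit the requested model."""


class IntegrationError(SwitchScanError, RuntimeError):
    """Numerical integration produced a non-finite state."""


class UndefinedGainError(ValidationError):
    """Information gain undefined because the phenotype entropy is zero."""


class SchemaError(ValidationError):
    """A results table is missing a required column."""
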