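"""Package exception hierarchy."""


class CircabpError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CircabpError, ValueError):
    """Invalid simulation or analysis configuration."""


class FormatError(CircabpError, ValueError):
    """Malformed input file (missing column, bad dialect, ...)."""


class InsufficientDataError(CircabpError, ValueError):
    """Too few readings to fit or evaluate a model."""


class FitRefusedError(InsufficientDataError):
    """A per-window model fit was refused; carries a reason code."""

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or reason)


class DomainError(CircabpError, ValueError):
    """Input outside the mathematical domain of an operation."""
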