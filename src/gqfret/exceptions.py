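"""Exception hierarchy shared across the package."""


class GqfretError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GqfretError):
    """Invalid configuration: bad enum value, weights not summing to one, ..."""


class TraceParseError(GqfretError):
    """Malformed trace table (ragged rows, non-numeric values, empty file)."""


class ManifestError(GqfretError):
    """Dataset manifest missing or missing required keys."""


class FitError(GqfretError):
    """Non-convergence of a least-squares fit; carries diagnostics."""

    def __init__(self, message, last_params=None, residual=None):
        super().__init__(message)
        self.last_params = last_params
        self.residual = residual


class NoSignalError(FitError):
    """All response values are ~0: there is nothing to fit."""
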