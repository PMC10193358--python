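"""Exception hierarchy."""


class BidisperseError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(BidisperseError, ValueError):
    """An argument is outside the documented domain."""


class ConvergenceError(BidisperseError, RuntimeError):
    """A rate solve failed to bracket or converge; carries (mu, nu)."""

    def __init__(self, message, mu=None, nu=None):
        super().__init__(message)
        self.mu = mu
        self.nu = nu


class RootSelectionError(BidisperseError, RuntimeError):
    """The rate polynomial did not yield exactly one admissible positive root."""


class ConfigurationError(BidisperseError, ValueError):
    """Inconsistent or incomplete run configuration."""


class DataValidationError(BidisperseError, ValueError):
    """Input data violate the model's domain (negative counts, rank deficiency, ...)."""


class TableParseError(BidisperseError, ValueError):
    """A look-up table file is malformed; carries the offending line number."""

    def __init__(self, message, line=None):
        super().__init__(message)
        self.line = line


class SamplerError(BidisperseError, RuntimeError):
    """The MCMC scheme hit a non-finite conditional; message carries a state dump."""
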