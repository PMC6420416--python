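"""Exception types shared across the package."""


class IlmqtlError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(IlmqtlError):
    """Invalid simulation or pipeline configuration."""


class PanelFormatError(IlmqtlError):
    """A panel / map / class table violates the documented file format."""


class DegenerateInputError(IlmqtlError):
    """Input collapses to nothing after filtering, or is too small to use."""


class MissingDataError(IlmqtlError):
    """An operation requires observed (or imputed) data that is absent."""
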