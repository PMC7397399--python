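"""Exception hierarchy shared across the pipeline stages."""


class DualflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DualflowError):
    """Invalid acquisition-method or pipeline configuration."""


class FormatError(DualflowError):
    """A data file violates its expected on-disk format."""


class ParameterError(DualflowError):
    """An operation parameter is out of its valid range."""


class ProcessingError(DualflowError):
    """A pipeline stage cannot proceed on otherwise valid input."""
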