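"""Exception types shared across the pipeline."""


class LymphomutError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LymphomutError, ValueError):
    """A configuration object or mode is invalid; message names the field."""


class DomainError(LymphomutError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class UndefinedValueError(DomainError):
    """A quantity is undefined for the given input (e.g. zero sequencing depth)."""


class StructuralError(LymphomutError, ValueError):
    """Two inputs that must share structure (e.g. a bin grid) do not."""


class InsufficientDataError(LymphomutError, ValueError):
    """Too few observations to compute the requested statistic."""
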