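"""Exception and warning hierarchy."""


class CellStateError(Exception):
    """Base class for all package errors."""


class FormatError(CellStateError):
    """An on-disk file does not conform to its declared format."""


class ValidationError(CellStateError):
    """Input data violate a documented precondition or invariant."""


class ConfigError(CellStateError):
    """A configuration value or file is invalid."""


class ModelIOError(CellStateError):
    """A model bundle is missing, truncated, or of an unknown version."""


class UncalibratedModelError(CellStateError):
    """Prediction was requested from a model without fitted calibrators."""


class CellStateWarning(UserWarning):
    """Base class for warnings emitted by the package."""
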