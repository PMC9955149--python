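"""Exception hierarchy shared across the package."""


class DiacascadeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DiacascadeError):
    """A schema is internally inconsistent or does not match the file."""


class InputError(DiacascadeError):
    """Input data violate a precondition (bad labels, empty table, ...)."""


class ParameterError(DiacascadeError):
    """A configuration parameter is out of its valid range."""


class TrainingError(DiacascadeError):
    """Numerical failure during network training."""


class ModelFormatError(DiacascadeError):
    """A serialized model file is unreadable or has the wrong version."""
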