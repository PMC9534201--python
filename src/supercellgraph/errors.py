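"""Exception hierarchy shared by all pipeline stages.

The CLI maps :class:`ValidationError` subclasses to exit code 2 and
:class:`DataError` subclasses to exit code 3.
"""


class SupercellGraphError(Exception):
    """Base class for all package errors."""


class ValidationError(SupercellGraphError):
    """Input violates a structural invariant (bad schema, bad config...)."""


class FormatError(ValidationError):
    """A file is not in the expected format."""


class ConfigError(ValidationError):
    """A configuration value is out of its legal range."""


class SchemaError(ValidationError):
    """Feature names / dimensions do not match between objects."""


class DataError(SupercellGraphError):
    """Input is structurally valid but unusable for the requested operation."""


class DataSizeError(DataError):
    """Too few rows/cells/supercells for the operation."""


class DegenerateDataError(DataError):
    """Data degenerate for the operation (all-constant features, zero bandwidth...)."""


class SpacingError(DataError):
    """Synthetic cluster centers could not be placed with the required separation."""
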