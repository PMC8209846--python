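"""Exception hierarchy shared across the package.

CLI exit codes map onto this hierarchy: :class:`ParameterError` (and its
subclass :class:`ConfigError`) exit with code 2, :class:`DataError` (and
:class:`SchemaError`) with code 3.
"""


class LrtcError(Exception):
    """Base class for all package errors."""


class ParameterError(LrtcError, ValueError):
    """An argument or specification field is outside its valid domain."""


class ConfigError(ParameterError):
    """A configuration file is malformed, has unknown keys or bad values."""


class DataError(LrtcError, ValueError):
    """Input data violate a precondition (shape, finiteness, degeneracy)."""


class SchemaError(DataError):
    """An HDF5 container does not match the expected on-disk layout."""
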