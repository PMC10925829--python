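"""Exception hierarchy shared across the pipeline.

Exit codes follow the CLI contract: 2 configuration/validation, 3 data,
4 numeric failure.
"""


class RootclinesError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(RootclinesError):
    """Invalid configuration or parameters outside documented ranges."""

    exit_code = 2


class SchemaError(ConfigError):
    """A table is missing mandatory columns or has inconsistent shape."""


class DataError(RootclinesError):
    """Input data is structurally valid but unusable (empty after filtering,
    zero-variance column, mismatched identifiers...)."""

    exit_code = 3


class ParseError(DataError):
    """A file failed to parse; the message names the offending record."""


class ModelError(DataError):
    """A statistical model cannot be fit on the given design."""


class GeometryError(DataError):
    """A root cross-section cannot be constructed from the parameters."""


class NumericError(RootclinesError):
    """An iterative procedure failed to converge."""

    exit_code = 4
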