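"""Exception hierarchy shared across the pipeline stages."""


class SomatomapError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SomatomapError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidGeometryError(SomatomapError, ValueError):
    """Requested geometry cannot be realised on the mesh."""


class InvalidEventError(SomatomapError, ValueError):
    """A task event falls outside the run."""


class RankError(SomatomapError, ValueError):
    """Design matrix is rank deficient."""


class InconsistencyError(SomatomapError, ValueError):
    """Inputs that must agree (conditions, ROIs, meshes) do not."""


class UnreachableError(SomatomapError, ValueError):
    """No path exists between two mesh vertices."""


class EmptyWinnerError(SomatomapError, ValueError):
    """A condition has no winner vertices where at least one is required."""

class CrossValidationError(SomatomapError, ValueError):
    """Not enough independent partitions for cross-validation."""


class InvalidCodeError(SomatomapError, ValueError):
    """Questionnaire frequency code outside the coding table."""


class SchemaError(SomatomapError, ValueError):
    """A tabular input is missing required columns."""
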