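"""Exception hierarchy shared by all pipeline stages.

Each error carries an ``exit_code`` so the command-line layer can map
failures onto its exit-code contract: 2 for schema/input problems, 3 for
degenerate geometry, 4 for statistical failures.
"""


class PelvimetricsError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class SchemaError(PelvimetricsError):
    """Input does not match the expected schema (missing column, landmark...)."""

    exit_code = 2


class InvalidLandmarkError(SchemaError):
    """A landmark coordinate is non-finite or otherwise unusable."""


class InvalidMaskError(SchemaError):
    """A mask contains values other than 0/1 (or True/False)."""


class ConfigError(SchemaError):
    """A generator or pipeline configuration value is infeasible."""


class BoundsError(SchemaError):
    """A phantom solid does not fit inside the requested grid."""


class ResolutionError(SchemaError):
    """A volume target is below the resolution of a single voxel."""


class DomainError(SchemaError):
    """A value outside the mathematical domain of a transform (e.g. log of <= 0)."""


class InconsistentReplicatesError(SchemaError):
    """Replicate measurements disagree on fields that are not fuzzy-flagged."""


class DataAlignmentError(SchemaError):
    """Two model fits that must share rows were fit on different rows."""


class GeometryError(PelvimetricsError):
    exit_code = 3


class DegenerateGeometryError(GeometryError):
    """Coincident or collinear landmarks make a measure undefined."""


class InconsistentDistancesError(GeometryError):
    """Three interlandmark distances violate the triangle inequality."""


class InfeasibleGeometryError(GeometryError):
    """Requested canal measurements admit no landmark configuration."""


class StatisticalError(PelvimetricsError):
    exit_code = 4


class UndefinedICCError(StatisticalError):
    """Zero between-subject variance: the ICC is 0/0."""


class CollinearityError(StatisticalError):
    """Rank-deficient design or singular predictor correlation matrix."""
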