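"""Exception hierarchy.

Every error raised by carcingeo derives from :class:`CarcingeoError`, split
into validation errors (bad inputs or parameters, CLI exit code 1) and
runtime errors (a computation that could not be completed, exit code 2).
"""


class CarcingeoError(Exception):
    """Base class for all carcingeo errors."""


class ValidationError(CarcingeoError):
    """Invalid input data or parameters."""


class ParameterError(ValidationError):
    """A model or generator parameter violates its invariant."""


class SchemaError(ValidationError):
    """A tabular input is missing or mistypes a required column."""


class FormatError(ValidationError):
    """A file could not be parsed in its declared format."""


class ComputationError(CarcingeoError):
    """A well-formed input on which the requested quantity is undefined."""


class DegenerateGeometryError(ComputationError):
    """Too few / collinear points for a plane, or coincident landmarks."""


class UndefinedLandmarkError(ComputationError):
    """A landmark construction has no (unique) solution, e.g. a line
    parallel to the plane it should intersect."""


class OrientationError(ComputationError):
    """The dorsal reference cannot orient the aperture-plane normal."""


class InfeasiblePlacementError(ComputationError):
    """No point on the shell surface realises the requested attachment."""


class ResolutionError(ValidationError):
    """Voxel size too coarse for the smallest structure of interest."""


class ExtractionError(ComputationError):
    """Isosurface extraction failed (e.g. empty occupancy volume)."""


class UndefinedTestError(ComputationError):
    """A statistical test is undefined on the given samples."""
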