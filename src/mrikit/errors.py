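"""Exception hierarchy.

Every error raised by the library derives from :class:`MRIKitError` so that
callers (and the CLI) can distinguish data/model problems from programming
errors. Usage errors at the command line are handled by the CLI layer.
"""


class MRIKitError(Exception):
    """Base class for all mrikit errors."""


class FormatError(MRIKitError):
    """A file is not valid NIfTI-1 / JSON / session format."""


class DimensionalityError(MRIKitError):
    """Array dimensionality outside the supported 2-5 range for the operation."""


class GeometryError(MRIKitError):
    """Shapes or voxel grids are incompatible."""


class ParameterError(MRIKitError):
    """A parameter value is outside its valid domain."""


class PreconditionError(MRIKitError):
    """An operation precondition is violated (e.g. empty initial outline)."""


class DegenerateInputError(MRIKitError):
    """Input carries no usable signal (e.g. all-constant image for clustering)."""


class DataError(MRIKitError):
    """Input data insufficient for the model (e.g. too few echoes)."""


class MetadataError(MRIKitError):
    """Acquisition metadata inconsistent (e.g. non-monotone echo times)."""


class ConsistencyError(MRIKitError):
    """Cross-object invariant violated (e.g. hemisphere not inside brain)."""


class CapabilityError(MRIKitError):
    """A registration engine does not support the requested transform model."""
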