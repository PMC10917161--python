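"""Exception hierarchy for netpyramid."""


class NetPyramidError(Exception):
    """Base class for all package-specific errors."""


class StructureError(NetPyramidError):
    """Atlas table violates structural constraints (duplicate ids/names, bad tree)."""


class MappingError(NetPyramidError):
    """A label cannot be mapped through the atlas hierarchy."""


class ConfigurationError(NetPyramidError):
    """A parameter is outside its documented range (e.g. band beyond Nyquist)."""


class DegenerateInputError(NetPyramidError):
    """Input is degenerate for the requested operation (zero variance, constant series)."""


class EmptyNodeError(NetPyramidError):
    """A parcel has no member voxels in the supplied labelling."""


class AssemblyError(NetPyramidError):
    """A feature matrix cannot be assembled (missing subject/node values)."""


class StratificationError(NetPyramidError):
    """Cross-validation folds cannot be stratified with both classes present."""


class PipelineError(NetPyramidError):
    """A pipeline stage failed or the configuration is invalid."""
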