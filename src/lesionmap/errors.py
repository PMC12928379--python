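"""Exception hierarchy for the lesion-mapping pipeline."""


class LesionMapError(Exception):
    """Base class for all lesionmap errors."""


class GridMismatchError(LesionMapError):
    """Two volumes do not share a compatible voxel grid."""


class EmptyCohortError(LesionMapError):
    """An operation that needs at least one subject received none."""


class EmptyAtlasError(LesionMapError):
    """A parcellation contains no nonzero labels."""


class EmptyBundleError(LesionMapError):
    """A tract bundle contains no streamlines."""


class ParameterError(LesionMapError):
    """A parameter is outside its valid range."""
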