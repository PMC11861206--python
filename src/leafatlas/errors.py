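"""Exception hierarchy for leafatlas."""


class LeafAtlasError(Exception):
    """Base class for all leafatlas errors."""


class MalformedGridError(LeafAtlasError):
    """A digitizer point file does not obey the 5n+1 acquisition rule."""


class TooFewTransectsError(MalformedGridError):
    """A digitizer grid has fewer than two transects."""


class DegenerateGeometryError(LeafAtlasError):
    """Input geometry is degenerate (zero-area triangle, collinear cloud, ...)."""


class TopologyError(LeafAtlasError):
    """Mesh topology violates the disk-with-one-boundary-loop assumption."""


class UnsupportedFormatError(LeafAtlasError):
    """Unknown mesh file format or non-triangular elements."""


class MissingRolesError(LeafAtlasError):
    """A mesh operation requires vertex role tags that are absent."""


class ConfigError(LeafAtlasError):
    """Invalid stage configuration (sector bounds, thresholds, ...)."""


class FeatureError(LeafAtlasError):
    """A feature cannot be computed from the given inputs."""


class IdentificationError(LeafAtlasError):
    """Atlas construction or identification failed (mismatched vectors, ...)."""
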