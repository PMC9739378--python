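"""Exception hierarchy.

Exit-code mapping for the CLI: configuration errors (2), input errors (3),
geometry/numeric errors (4).
"""


class GaitBlurError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GaitBlurError):
    """Invalid parameter value (non-positive length, even kernel, ...)."""


class InputError(GaitBlurError):
    """Structurally invalid or mismatched input data."""


class GeometryError(GaitBlurError):
    """Degenerate geometry (coincident points, collinear segments, ...)."""


class ProjectionError(GeometryError):
    """Point cannot be projected (non-positive depth in the camera frame)."""


class RenderError(GaitBlurError):
    """Rendering failed (e.g. a keypoint lies behind the camera)."""


class UnsupportedFeatureError(GaitBlurError):
    """Recognised but unsupported input feature (e.g. lens distortion)."""
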