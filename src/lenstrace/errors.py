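"""Exception hierarchy for lenstrace."""


class LenstraceError(Exception):
    """Base class for all lenstrace errors."""


class ContourError(LenstraceError):
    """Invalid contour (too few points, non-finite coordinates, ...)."""


class DescriptorError(LenstraceError):
    """Invalid descriptor set or descriptor-space operation."""


class DegenerateShapeError(DescriptorError):
    """Shape with no first-harmonic extent (|c(1)| = 0)."""


class DatabaseError(LenstraceError):
    """Shape database loading / validation failure."""


class EyeDetectionError(LenstraceError):
    """No usable left/right eye pair could be found."""


class TiltError(EyeDetectionError):
    """Head horizontal tilt exceeds the usable limit."""


class EmptyEdgeMapError(LenstraceError):
    """Edge map contains no edge pixels; distance field undefined."""


class ExtractionError(LenstraceError):
    """No acceptable lens hypothesis was found in any shape class."""


class ConfigError(LenstraceError):
    """Invalid or unknown configuration key/value."""
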