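"""Package-specific error conditions raised by pipeline stages."""


class PllpQuantError(Exception):
    """Base class for all package errors."""


class BimodalSeparationError(PllpQuantError):
    """Histogram never became bimodal: no minimum threshold exists."""


class EmptyMaskError(PllpQuantError):
    """A 2D mask ended up with no foreground pixels."""


class DegenerateMaskError(PllpQuantError):
    """Mask too small/degenerate for a moment-ellipse fit."""


class InfeasibleGeometryError(PllpQuantError):
    """Requested cell packing cannot be realized in the tissue ellipsoid."""


class SegmentationEmptyError(PllpQuantError):
    """Segmentation or filtering produced zero labels."""


class UndefinedStatisticError(PllpQuantError):
    """A statistic is undefined for the given input (e.g. 0/0 ratio)."""
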