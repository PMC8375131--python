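"""Exception types raised by the analysis pipeline."""


class SpherinvError(Exception):
    """Base class for all package-specific errors."""


class SceneCapacityError(SpherinvError):
    """Requested invading-cell count cannot plausibly fit the annulus."""


class DegenerateHistogramError(SpherinvError):
    """Histogram cannot be reduced to a bimodal shape (Minimum method)."""


class NoCoreFoundError(SpherinvError):
    """No connected component survived the core size filter."""


class EmptySegmentationError(SpherinvError):
    """Thresholding produced an empty object mask."""


class ProfileError(SpherinvError):
    """Radial profile violates a precondition (e.g. no core plateau)."""


class SchemaError(SpherinvError):
    """Tabular input is missing required columns."""
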