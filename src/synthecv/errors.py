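"""Exception hierarchy for the synthecv pipeline.

Every stage raises a subclass of :class:`SynthEcvError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class SynthEcvError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(SynthEcvError):
    """Invalid cohort or pipeline configuration."""


class GeometryError(SynthEcvError):
    """Phantom geometry violates its invariants or the raster bounds."""


class RenderingError(SynthEcvError):
    """Tissue parameter combination cannot be rendered (non-physical T1)."""


class SegmentationError(SynthEcvError):
    """A segmentation backend failed to produce valid contours."""


class RefinementError(SynthEcvError):
    """Mask refinement produced an empty or invalid measurement mask."""


class MeasurementError(SynthEcvError):
    """Value extraction failed (e.g. empty measurement mask)."""


class FittingError(SynthEcvError):
    """Hematocrit regression could not be fitted."""


class EcvComputationError(SynthEcvError):
    """Non-physiological inputs to the ECV formula."""


class FormatError(SynthEcvError):
    """On-disk data does not match the expected format or schema."""


class UsageError(SynthEcvError):
    """Invalid combination of arguments (e.g. model/map phase mismatch)."""
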