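"""Exception hierarchy for the callosal-angle pipeline.

Every stage raises a distinct, catchable error type so callers (and the CLI)
can name the failing stage without string matching.
"""


class CaliperError(Exception):
    """Base class for all package errors."""


class VolumeError(CaliperError):
    """Problems with volume input: missing file, non-3D data, bad header."""


class NonVolumeError(VolumeError):
    """Input is not a 3D volume (e.g. a 4D time series)."""


class ObliqueAffineError(VolumeError):
    """Affine too oblique to reorient by axis permutation/flip alone."""


class DegenerateAxisError(VolumeError):
    """A volume axis has zero physical extent."""


class ConstantImageError(VolumeError):
    """Intensity standardization is undefined for a constant image."""


class LandmarkError(CaliperError):
    """Invalid or inconsistent AC/PC landmarks."""


class FrameMismatchError(LandmarkError):
    """Two landmark sets are not expressed in a common coordinate frame."""


class GeometryError(CaliperError):
    """Degenerate plane or line geometry."""


class SegmentationError(CaliperError):
    """Invalid ventricle mask (missing class, tiny component, bad labels)."""


class SeparationError(CaliperError):
    """The two ventricles cannot be separated by a line."""


class MedialWallError(CaliperError):
    """Too few ray hits to define a medial wall."""


class WallFitError(CaliperError):
    """No line through the base point gathers enough wall-point inliers."""


class PipelineStageError(CaliperError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
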