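"""Exception hierarchy for seegseg.

Per-electrode failures derive from :class:`SegmentationError` so that an
implant run can record them and keep going; input/format problems derive
from :class:`SeegsegError` directly and abort.
"""


class SeegsegError(Exception):
    """Base class for all seegseg errors."""


class FormatError(SeegsegError):
    """An input file could not be read or has the wrong structure."""


class FiducialParseError(FormatError):
    """A fiducial file line or label pairing is malformed."""


class GridMismatchError(SeegsegError):
    """Two volumes do not share the same voxel grid (shape + affine)."""


class ThresholdError(SeegsegError):
    """Automatic threshold selection failed (no interior histogram minimum)."""


class SegmentationError(SeegsegError):
    """Base class for per-electrode algorithm failures (recorded, not fatal)."""


class DegenerateAxisError(SegmentationError):
    """Two coincident points were used to define a line direction."""


class EmptyRegionError(SegmentationError):
    """A cubic region holds no mass above the threshold."""


class ConvergenceError(SegmentationError):
    """Centroid iteration did not converge within ``max_iter`` steps."""

    def __init__(self, message, last_point=None):
        super().__init__(message)
        self.last_point = last_point


class ElectrodeNotFoundError(SegmentationError):
    """No electrode signal could be located for a trajectory."""


class PhantomSpecError(SeegsegError):
    """A phantom specification is inconsistent or does not fit its grid."""
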