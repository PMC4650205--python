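"""Exception hierarchy for the leafroll pipeline.

Every error raised by the package derives from :class:`LeafrollError`, so
batch drivers can trap pipeline failures per strip without masking genuine
programming errors.
"""


class LeafrollError(Exception):
    """Base class for all leafroll-specific errors."""


# --- digitizer ---------------------------------------------------------


class NoForeground(LeafrollError):
    """Binarisation produced an empty mask after speck cleanup."""


class DegenerateSkeleton(LeafrollError):
    """Skeleton's longest path is too short to describe a strip."""


class CyclicSkeleton(LeafrollError):
    """Skeleton contains a cycle larger than the allowed tolerance."""


class ChainTooShort(LeafrollError):
    """Skeleton chain has fewer pixels than the requested sample count."""


# --- spline / curvature ------------------------------------------------


class TraceOutOfRange(LeafrollError):
    """Requested smoother trace outside the attainable interval (2, n]."""


class BisectionFailure(LeafrollError):
    """Penalty search did not reach the trace tolerance within budget."""


class ZeroSpeed(LeafrollError):
    """Degenerate parameterisation: curve speed vanished on the grid."""


# --- convex hull -------------------------------------------------------


class DegenerateHull(LeafrollError):
    """Fewer than three non-collinear points: no 2-D hull exists."""


class NonPositiveInput(LeafrollError):
    """Length or diameter must be strictly positive."""


# --- PEG calibration ---------------------------------------------------


class OutOfRange(LeafrollError):
    """PEG concentration outside the calibrated range."""


class NoRootInRange(LeafrollError):
    """Requested osmotic potential is unreachable on the calibrated range."""


class RankDeficient(LeafrollError):
    """Too few distinct calibration points for the polynomial degree."""


# --- synthetic ---------------------------------------------------------


class InvalidSpec(LeafrollError):
    """Shape specification violates its invariants."""


# --- pipeline ----------------------------------------------------------


class EmptyManifest(LeafrollError):
    """Manifest resolves to zero input strips."""


class SingularDesign(LeafrollError):
    """ANOVA design matrix is singular (missing factor levels/cells)."""
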