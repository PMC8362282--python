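"""Exception hierarchy for disccalib.

All library-specific failures derive from :class:`DiscCalibError` so callers
can catch one base class at pipeline boundaries.
"""


class DiscCalibError(Exception):
    """Base class for all disccalib errors."""


class GeometryError(DiscCalibError):
    """A contour is degenerate or a geometric construction is impossible
    (self-intersecting polygon, zero area, mid-sagittal line missing the
    nucleus, ...)."""


class ContainmentError(GeometryError):
    """The nucleus contour is not strictly inside the disc contour."""


class InfeasiblePlacementError(GeometryError):
    """A requested (P1, P2) placement would push part of the nucleus outside
    the disc boundary."""


class UndefinedStatisticError(DiscCalibError):
    """A reliability statistic is undefined for the given data (chance
    agreement of 1 for kappa, zero total-score variance for alpha)."""


class SingularSectionError(DiscCalibError):
    """A cross-section has no load-bearing material (all-void section or
    zero stiffness)."""


class MappingError(DiscCalibError):
    """A computed validation entry has no matching reference value."""


class CohortGenerationError(DiscCalibError):
    """Synthetic cohort generation failed (e.g. repeated infeasible jittered
    placements)."""
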