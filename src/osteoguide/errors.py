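"""Exception hierarchy for the guide-generation pipeline.

Every contract violation raises a subclass of :class:`OsteoguideError` so the
CLI can map failures onto stable exit codes (usage/parameter -> 2,
geometry -> 3, plan conflict -> 4).
"""


class OsteoguideError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ParameterError(OsteoguideError, ValueError):
    """An argument violates an operation's precondition (e.g. n_grafts < 1)."""

    exit_code = 2


class FormatError(OsteoguideError):
    """A mesh file could not be parsed (corrupt or unsupported format)."""

    exit_code = 2


class ContentError(OsteoguideError):
    """A mesh file parsed but holds no usable geometry (empty mesh)."""

    exit_code = 2


class GeometryError(OsteoguideError):
    """Geometric precondition failed: non-watertight Boolean operand,
    degenerate principal axis, coincident resection origins, ..."""

    exit_code = 3


class ConstructionError(GeometryError):
    """A guide feature could not be realised (e.g. a slot slab misses the
    guide shell entirely)."""


class PlacementError(GeometryError):
    """A screw hole collides with a cutting slot or lies off the guide."""


class PlanConflictError(OsteoguideError):
    """Two graft segments claim overlapping fibular intervals, or the plan
    exceeds the harvestable fibular span."""

    exit_code = 4


class CapacityError(PlanConflictError):
    """Total designed graft length plus gaps and kerf allowances exceeds the
    harvestable fibula span."""
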