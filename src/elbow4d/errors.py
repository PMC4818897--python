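"""Exception hierarchy for elbow4d.

Every precondition named in the public API raises one of these, so callers
(and the CLI) can distinguish bad input data from bad arguments.
"""


class Elbow4DError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(Elbow4DError):
    """File could not be parsed as a mesh (truncated, wrong format...)."""


class EmptyMeshError(MeshFormatError):
    """A mesh file parsed but contains zero triangles."""


class NotWatertightError(Elbow4DError):
    """An operation requiring a closed surface received an open mesh."""

    def __init__(self, open_edge_count: int, name: str = "mesh"):
        self.open_edge_count = int(open_edge_count)
        super().__init__(
            f"{name} is not watertight: {open_edge_count} boundary edge(s)"
        )


class DegenerateLandmarksError(Elbow4DError):
    """Landmark points are collinear/coincident; no unique circle exists."""

    def __init__(self, group: str, triangle_area: float):
        self.group = group
        self.triangle_area = float(triangle_area)
        super().__init__(
            f"degenerate landmarks: {group} (triangle area {triangle_area:.3g} mm^2)"
        )


class UnstableAxisError(Elbow4DError):
    """Ring centers nearly coincide; the axis direction is ill-conditioned."""


class UndefinedICCError(Elbow4DError):
    """Ratings have zero total variance; the ICC is undefined."""


class DegenerateTestError(Elbow4DError):
    """A t statistic is undefined (zero variance with nonzero mean shift)."""


class PhantomSpecError(Elbow4DError):
    """A phantom specification is geometrically inconsistent."""


class ResourceLimitError(Elbow4DError):
    """A voxel grid would exceed the configured cell budget."""
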