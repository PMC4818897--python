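"""Rigid flexion-extension kinematics of the forearm unit.

The ulna and radius move as one rigid body about the fitted hinge axis;
the humerus stays fixed.  Flexion is positive, extension deficit negative,
and every pose is built directly from the reference pose (absolute angles),
never by chaining increments, so long sweeps accumulate no drift.

The CT reference pose's flexion angle is a required configuration input:
scans are taken with the elbow in one position and the simulation is only
as calibrated as that measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh import TriMesh
from .rings import HingeAxis


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @property
    def is_proper(self) -> bool:
        R = self.rotation
        return bool(
            np.allclose(R @ R.T, np.eye(3), atol=1e-9)
            and np.linalg.det(R) > 0
        )


def rotation_about_axis(axis: HingeAxis, angle_deg: float) -> RigidTransform:
    """Rotation by ``angle_deg`` about the hinge line; axis points stay fixed."""
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis.direction).as_matrix()
    p = axis.point
    return RigidTransform(R, p - R @ p)


def pose_forearm(
    mesh: TriMesh,
    axis: HingeAxis,
    angle_deg: float,
    reference_angle_deg: float = 0.0,
) -> TriMesh:
    """The forearm mesh posed at an absolute flexion angle.

    ``reference_angle_deg`` is the flexion angle of the mesh as given
    (the scanned position); the applied rotation is the difference.
    """
    t = rotation_about_axis(axis, angle_deg - reference_angle_deg)
    return mesh.transformed(t.rotation, t.translation)


@dataclass
class PoseSequence:
    """Ordered flexion angles plus the transform realizing each one."""

    axis: HingeAxis
    angles: np.ndarray
    transforms: list[RigidTransform] = field(repr=False)
    reference_angle_deg: float = 0.0


def pose_sequence(
    axis: HingeAxis,
    start: float,
    stop: float,
    step: float,
    reference_angle_deg: float = 0.0,
) -> PoseSequence:
    """Angles from start to stop by step, both endpoints included.

    When (stop - start) is not a multiple of step, the final frame is the
    stop angle appended after the last full step.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if start >= stop:
        raise ValueError("start must be less than stop")
    n = int(np.floor((stop - start) / step + 1e-9))
    angles = start + step * np.arange(n + 1)
    if angles[-1] < stop - 1e-9:
        angles = np.append(angles, stop)
    transforms = [
        rotation_about_axis(axis, a - reference_angle_deg) for a in angles
    ]
    return PoseSequence(
        axis=axis,
        angles=angles,
        transforms=transforms,
        reference_angle_deg=reference_angle_deg,
    )
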