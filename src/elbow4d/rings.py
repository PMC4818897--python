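"""The "two rings" hinge-axis construction for the distal humerus.

The elbow flexion-extension axis wanders slightly through the arc of motion
in vivo, but its mean is well approximated by the line joining the centers
of the trochlea and the capitellum.  This module fits a circle ("ring") to
three or more points plotted on each articular surface and takes the axis
through the two ring centers, oriented trochlea (medial) -> capitellum
(lateral).

Landmark JSON format::

    {"trochlea": [[x,y,z], ...], "capitellum": [[x,y,z], ...],
     "source": "observer1-session1"}

with coordinates in mm.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateLandmarksError, UnstableAxisError

#: Minimum triangle area (mm^2) below which a landmark triple is degenerate.
COLLINEAR_AREA_TOL = 1e-9

#: Ring centers closer than this (mm) make the axis direction ill-conditioned.
MIN_CENTER_SEPARATION = 1.0


@dataclass
class LandmarkSet:
    """>=3 points on the trochlea and >=3 on the capitellum (mm)."""

    trochlea_points: np.ndarray
    capitellum_points: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.trochlea_points = np.atleast_2d(
            np.asarray(self.trochlea_points, dtype=float)
        )
        self.capitellum_points = np.atleast_2d(
            np.asarray(self.capitellum_points, dtype=float)
        )
        for name, pts in (
            ("trochlea", self.trochlea_points),
            ("capitellum", self.capitellum_points),
        ):
            if pts.shape[0] < 3 or pts.shape[1] != 3:
                raise ValueError(f"{name} needs at least 3 points of dimension 3")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "LandmarkSet":
        with open(os.fspath(path)) as fh:
            data = json.load(fh)
        return cls(
            np.asarray(data["trochlea"], float),
            np.asarray(data["capitellum"], float),
            source=data.get("source", ""),
        )

    def to_json(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            json.dump(
                {
                    "trochlea": self.trochlea_points.tolist(),
                    "capitellum": self.capitellum_points.tolist(),
                    "source": self.source,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


@dataclass
class Ring:
    """A circle in 3D: center (mm), radius (mm), unit normal."""

    center: np.ndarray
    radius: float
    normal: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n > 0:
            self.normal = self.normal / n


@dataclass
class HingeAxis:
    """A line: point on the axis (mm) plus unit direction, with fit diagnostics."""

    point: np.ndarray
    direction: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        self.direction = self.direction / np.linalg.norm(self.direction)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "HingeAxis":
        with open(os.fspath(path)) as fh:
            data = json.load(fh)
        return cls(
            np.asarray(data["point"], float),
            np.asarray(data["direction"], float),
            diagnostics=data.get("diagnostics", {}),
        )

    def to_json(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            json.dump(
                {
                    "point": self.point.tolist(),
                    "direction": self.direction.tolist(),
                    "diagnostics": self.diagnostics,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def circumcircle3(p1, p2, p3, group: str = "landmarks") -> Ring:
    """The unique circle through three non-collinear 3D points.

    Uses the barycentric circumcenter formula; the normal follows the
    right-hand rule on (p1, p2, p3).
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u = p2 - p1
    w = p3 - p1
    n = np.cross(u, w)
    area = 0.5 * np.linalg.norm(n)
    scale = max(np.linalg.norm(u), np.linalg.norm(w), 1.0)
    if area <= COLLINEAR_AREA_TOL * scale**2:
        raise DegenerateLandmarksError(group, area)

    a2 = np.dot(p2 - p3, p2 - p3)
    b2 = np.dot(p1 - p3, p1 - p3)
    c2 = np.dot(p1 - p2, p1 - p2)
    # barycentric weights of the circumcenter
    wa = a2 * (b2 + c2 - a2)
    wb = b2 * (c2 + a2 - b2)
    wc = c2 * (a2 + b2 - c2)
    center = (wa * p1 + wb * p2 + wc * p3) / (wa + wb + wc)
    radius = float(np.linalg.norm(p1 - center))
    return Ring(center=center, radius=radius, normal=n / (2 * area))


def fit_ring(points: np.ndarray, group: str = "landmarks") -> Ring:
    """Circle through >=3 points; exact circumcircle for 3, least squares beyond.

    For more than three points: total-least-squares plane (SVD), then a
    Kasa algebraic circle fit in that plane.  RMS of the 3D point-to-circle
    distances is reported in ``rms_residual``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 3:
        raise ValueError("need at least 3 points to fit a ring")
    if len(points) == 3:
        return circumcircle3(points[0], points[1], points[2], group=group)

    centroid = points.mean(axis=0)
    q = points - centroid
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    scale = max(s[0], 1.0)
    if s[1] <= 1e-12 * scale:
        raise DegenerateLandmarksError(group, float(s[1]))
    normal = vt[2]
    e1, e2 = vt[0], vt[1]
    x = q @ e1
    y = q @ e2
    # Kasa fit: minimize sum((x-a)^2 + (y-b)^2 - r^2)^2, linear in (a, b, c)
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    (a, bb, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    radius = float(np.sqrt(c + a**2 + bb**2))
    center = centroid + a * e1 + bb * e2
    inplane = np.hypot(x - a, y - bb) - radius
    offplane = q @ normal
    rms = float(np.sqrt(np.mean(inplane**2 + offplane**2)))
    # orient the normal by the right-hand rule on the first three points
    ref = np.cross(points[1] - points[0], points[2] - points[0])
    if np.dot(ref, normal) < 0:
        normal = -normal
    return Ring(center=center, radius=radius, normal=normal, rms_residual=rms)


def two_rings(landmarks: LandmarkSet) -> HingeAxis:
    """Fit both articular rings and draw the axis through their centers.

    Axis point is the trochlear ring center; the direction points toward
    the capitellar ring center (medial -> lateral convention).
    """
    tro = fit_ring(landmarks.trochlea_points, group="trochlea")
    cap = fit_ring(landmarks.capitellum_points, group="capitellum")
    sep = cap.center - tro.center
    dist = float(np.linalg.norm(sep))
    if dist < MIN_CENTER_SEPARATION:
        raise UnstableAxisError(
            f"ring centers only {dist:.3g} mm apart; axis direction ill-conditioned"
        )
    direction = sep / dist

    def _angle(n):
        return float(np.degrees(np.arccos(np.clip(abs(np.dot(n, direction)), 0, 1))))

    diagnostics = {
        "trochlea_radius_mm": tro.radius,
        "capitellum_radius_mm": cap.radius,
        "inter_center_distance_mm": dist,
        "trochlea_normal_axis_angle_deg": _angle(tro.normal),
        "capitellum_normal_axis_angle_deg": _angle(cap.normal),
        "trochlea_rms_residual_mm": tro.rms_residual,
        "capitellum_rms_residual_mm": cap.rms_residual,
        "source": landmarks.source,
    }
    return HingeAxis(point=tro.center, direction=direction, diagnostics=diagnostics)


def axis_error(a: HingeAxis, b: HingeAxis) -> tuple[float, float]:
    """(angle in degrees, minimal line-line distance in mm) between two axes.

    The angle is orientation-agnostic (arccos of |dot|).
    """
    da, db = a.direction, b.direction
    angle = float(np.degrees(np.arccos(np.clip(abs(np.dot(da, db)), 0.0, 1.0))))
    w = b.point - a.point
    cross = np.cross(da, db)
    denom = np.linalg.norm(cross)
    if denom < 1e-12:  # parallel: distance from a.point's line to b.point
        dist = float(np.linalg.norm(w - np.dot(w, da) * da))
    else:
        dist = float(abs(np.dot(w, cross)) / denom)
    return angle, dist


def snap_to_surface(landmarks: LandmarkSet, mesh) -> LandmarkSet:
    """Project each landmark onto the nearest point of the humerus surface."""
    import trimesh as _tm

    m = mesh.to_trimesh()
    tro, _, _ = _tm.proximity.closest_point(m, landmarks.trochlea_points)
    cap, _, _ = _tm.proximity.closest_point(m, landmarks.capitellum_points)
    return LandmarkSet(tro, cap, source=landmarks.source)
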