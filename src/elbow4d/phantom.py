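"""Parametric hinge-elbow phantom with analytically known ground truth.

The phantom trades anatomical realism for exact geometry: every articular
surface is a solid of revolution about the true hinge axis (the x-axis), so
the true flexion-extension axis, the two articular rings, and the flexion
angle at which a designed osteophyte first contacts the opposing bone are
all available in closed form.

Construction
------------
* Humerus (static): a closed surface given in cylindrical polar form
  ``r(x, phi)`` about the axis - trochlea cylinder (radius ``trochlea_radius``
  over the central band), a spherical capitellum (radius
  ``capitellum_radius`` centred ``inter_center_distance`` lateral), a narrow
  neck, a radial shaft sector standing in for the humeral diaphysis, and
  optional spherical osteophyte bosses seated on the trochlea surface.
* Forearm (moving): a curved annular-sector "cup" wrapped around the
  trochlea with radial ``clearance``, spanning 120 deg of circumference,
  plus a radial shaft sector; optional osteophyte bosses protrude inward
  from the cup.

Contact geometry
----------------
A spherical boss of radius ``s`` seated on a circle of radius ``r_b`` about
the axis reaches the opposing surface of radius ``r_s`` over an angular
half-width ``beta`` with::

    cos(beta) = (r_b^2 + r_s^2 - s^2) / (2 r_b r_s)

so first contact with a cup edge (or articular-arc edge) at circumferential
station ``phi`` happens at a flexion angle that is a simple difference of
angles - the closed form the tests and the end-to-end sweep check against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import trimesh as _tm

from .errors import PhantomSpecError
from .mesh import TriMesh
from .rings import HingeAxis, LandmarkSet, Ring

# Fixed layout constants (mm / degrees); the tunable quantities live in
# PhantomSpec.  The cup spans [CUP_START, CUP_END] at the reference pose
# (flexion 0), leaving a designed free arc of roughly [-85, 120+] deg even
# before osteophytes are added.
CUP_START_DEG = 120.0
CUP_END_DEG = 240.0
CUP_HALF_WIDTH = 5.0
CUP_WALL_THICKNESS = 4.0
NECK_RADIUS = 5.0
HUM_SHAFT_SECTOR_DEG = (65.0, 115.0)
FOREARM_SHAFT_SECTOR_DEG = (168.0, 192.0)
TROCHLEA_HALF_WIDTH = 6.0
_EDGE_EPS = 1e-4  # rad/mm smear used to realize sharp steps with finite faces


@dataclass
class Osteophyte:
    """A spherical bony boss.

    ``center_angle_deg`` is the circumferential station of the boss center:
    in the (static) humerus frame for ``attached_to="humerus"``, in the cup
    frame for ``attached_to="forearm"``.  ``x_mm`` is the station along the
    axis; ``size_mm`` is the sphere radius.
    """

    attached_to: str
    center_angle_deg: float
    size_mm: float
    x_mm: float = 0.0


@dataclass
class PhantomSpec:
    """Dimensions of the phantom (mm, degrees) and the mesh resolution."""

    trochlea_radius: float = 10.0
    capitellum_radius: float = 8.0
    inter_center_distance: float = 30.0
    shaft_length: float = 35.0
    clearance: float = 1.0
    trochlea_arc_deg: float = 360.0
    osteophytes: list[Osteophyte] = field(default_factory=list)
    mesh_resolution: float = 0.5
    seed: int = 0

    @property
    def cup_inner_radius(self) -> float:
        return self.trochlea_radius + self.clearance

    def validate(self) -> None:
        if min(
            self.trochlea_radius,
            self.capitellum_radius,
            self.inter_center_distance,
            self.shaft_length,
            self.clearance,
            self.mesh_resolution,
        ) <= 0:
            raise PhantomSpecError("all dimensions must be positive")
        if self.inter_center_distance <= self.capitellum_radius + TROCHLEA_HALF_WIDTH:
            raise PhantomSpecError("capitellum overlaps the trochlea band")
        if not 0 < self.trochlea_arc_deg <= 360:
            raise PhantomSpecError("trochlea_arc_deg must be in (0, 360]")
        for o in self.osteophytes:
            if o.attached_to not in ("humerus", "forearm"):
                raise PhantomSpecError(f"unknown attachment {o.attached_to!r}")
            if o.size_mm <= 0:
                raise PhantomSpecError("osteophyte size must be positive")
            if o.size_mm >= self.clearance + CUP_WALL_THICKNESS:
                raise PhantomSpecError(
                    "osteophyte larger than the joint space geometry"
                )
            if abs(o.x_mm) + o.size_mm > TROCHLEA_HALF_WIDTH:
                raise PhantomSpecError(
                    "osteophyte footprint extends beyond the articular band"
                )
            if (
                o.attached_to == "forearm"
                and o.size_mm > self.clearance
                and self.trochlea_arc_deg >= 360
            ):
                raise PhantomSpecError(
                    "a forearm boss deeper than the clearance against a full "
                    "trochlear ring impinges at every angle; limit "
                    "trochlea_arc_deg to make contact angle-selective"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomSpec":
        data = dict(data)
        data["osteophytes"] = [
            o if isinstance(o, Osteophyte) else Osteophyte(**o)
            for o in data.get("osteophytes", [])
        ]
        return cls(**data)


@dataclass
class Phantom:
    """Generated meshes plus the analytic ground truth they realize."""

    humerus_mesh: TriMesh
    forearm_mesh: TriMesh
    true_axis: HingeAxis
    true_rings: tuple[Ring, Ring]
    spec: PhantomSpec


# -- contact closed forms --------------------------------------------------


def _beta_deg(r_boss: float, r_surface: float, size: float) -> float | None:
    """Angular half-width over which a boss reaches the opposing surface."""
    c = (r_boss**2 + r_surface**2 - size**2) / (2 * r_boss * r_surface)
    if c >= 1.0:
        return None  # boss shallower than the clearance: no contact anywhere
    return math.degrees(math.acos(max(c, -1.0)))


def _norm_angle(a: float, center: float = 60.0) -> float:
    """Wrap to (center-180, center+180]."""
    return (a - center + 180.0) % 360.0 - 180.0 + center


def contact_angles(spec: PhantomSpec, osteo: Osteophyte) -> dict:
    """Closed-form first-contact flexion angles for one osteophyte.

    Returns ``{"flexion": angle_or_None, "extension": angle_or_None}``:
    the boss impinges for flexion beyond the "flexion" angle and for
    extension beyond (below) the "extension" angle.
    """
    r_in = spec.cup_inner_radius
    r_t = spec.trochlea_radius
    if osteo.attached_to == "humerus":
        beta = _beta_deg(r_t, r_in, osteo.size_mm)
        if beta is None:
            return {"flexion": None, "extension": None}
        phi = osteo.center_angle_deg
        return {
            "flexion": _norm_angle(phi - beta - CUP_END_DEG),
            "extension": _norm_angle(phi + beta - CUP_START_DEG),
        }
    beta = _beta_deg(r_in, r_t, osteo.size_mm)
    if beta is None or spec.trochlea_arc_deg >= 360:
        return {"flexion": None, "extension": None}
    t0, t1 = _trochlea_arc_bounds(spec)
    psi = osteo.center_angle_deg
    return {
        "flexion": _norm_angle(t0 - beta - psi),
        "extension": _norm_angle(t1 + beta - psi),
    }


def humeral_osteophyte_for_contact(
    spec: PhantomSpec,
    contact_angle_deg: float,
    size_mm: float = 3.0,
    side: str = "flexion",
    x_mm: float = 0.0,
) -> Osteophyte:
    """A humeral boss of given size whose station is solved so that first
    contact occurs exactly at ``contact_angle_deg`` on the chosen side."""
    beta = _beta_deg(spec.trochlea_radius, spec.cup_inner_radius, size_mm)
    if beta is None:
        raise PhantomSpecError(
            f"size {size_mm} mm does not exceed the clearance; no contact possible"
        )
    if side == "flexion":
        phi = CUP_END_DEG + contact_angle_deg + beta
    elif side == "extension":
        phi = CUP_START_DEG + contact_angle_deg - beta
    else:
        raise ValueError("side must be 'flexion' or 'extension'")
    return Osteophyte(
        attached_to="humerus",
        center_angle_deg=_norm_angle(phi),
        size_mm=size_mm,
        x_mm=x_mm,
    )


def _trochlea_arc_bounds(spec: PhantomSpec) -> tuple[float, float]:
    """Articular arc [t0, t1] (deg); the recess is centered opposite 60 deg."""
    half = spec.trochlea_arc_deg / 2.0
    return 60.0 - half, 60.0 + half


# -- mesh construction -----------------------------------------------------


def _dedupe(values: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    values = np.sort(values)
    keep = np.concatenate([[True], np.diff(values) > tol])
    return values[keep]


def _refined_stations(base: np.ndarray, spans, fine: float) -> np.ndarray:
    """Base stations plus fine sampling over each (lo, hi) span."""
    extra = [base]
    for lo, hi in spans:
        if hi > lo:
            extra.append(np.arange(lo, hi + fine / 2, fine))
    return _dedupe(np.concatenate(extra))


def _boss_radial(
    r_seat: float, s: float, dx: np.ndarray, dphi: np.ndarray, outward: bool
) -> np.ndarray:
    """Radial coordinate of a spherical boss surface seated at radius r_seat.

    ``outward=True`` gives the far branch (boss on a convex surface, e.g. the
    trochlea); ``False`` the near branch (boss protruding inward from the
    cup's inner face).  NaN where the sphere is not crossed.
    """
    disc = s**2 - dx[:, None] ** 2 - (r_seat * np.sin(dphi[None, :])) ** 2
    root = np.sqrt(np.maximum(disc, 0.0))
    base = r_seat * np.cos(dphi[None, :])
    r = base + root if outward else base - root
    r[disc < 0] = np.nan
    return r


def _wrap_dphi(phi: np.ndarray, center_deg: float) -> np.ndarray:
    d = phi - math.radians(center_deg)
    return (d + np.pi) % (2 * np.pi) - np.pi


def _tube_mesh(
    x: np.ndarray, phi: np.ndarray, r: np.ndarray, close_start: bool, close_end: bool
) -> TriMesh:
    """Closed surface from r(x_i, phi_j) sampled on a full angular grid."""
    nx, nphi = r.shape
    y = r * np.cos(phi)[None, :]
    z = r * np.sin(phi)[None, :]
    verts = np.column_stack(
        [np.repeat(x, nphi), y.ravel(), z.ravel()]
    )
    faces = []
    for i in range(nx - 1):
        a = i * nphi + np.arange(nphi)
        b = i * nphi + (np.arange(nphi) + 1) % nphi
        c = a + nphi
        d = b + nphi
        faces.append(np.column_stack([a, b, c]))
        faces.append(np.column_stack([b, d, c]))
    faces = [np.concatenate(faces)]
    apexes = []
    if close_start:
        apex = len(verts) + len(apexes)
        apexes.append([x[0], 0.0, 0.0])
        j = np.arange(nphi)
        faces.append(np.column_stack([np.full(nphi, apex), (j + 1) % nphi, j]))
    if close_end:
        apex = len(verts) + len(apexes)
        apexes.append([x[-1], 0.0, 0.0])
        j = (nx - 1) * nphi + np.arange(nphi)
        jn = (nx - 1) * nphi + (np.arange(nphi) + 1) % nphi
        faces.append(np.column_stack([np.full(nphi, apex), j, jn]))
    if apexes:
        verts = np.vstack([verts, np.asarray(apexes)])
    return _finalize(verts, np.concatenate(faces))


def _finalize(verts: np.ndarray, faces: np.ndarray) -> TriMesh:
    m = _tm.Trimesh(verts, faces, process=False)
    _tm.repair.fix_normals(m)
    if m.volume < 0:
        m.invert()
    if not m.is_watertight:
        raise PhantomSpecError("internal error: generated mesh is not watertight")
    return TriMesh(np.asarray(m.vertices), np.asarray(m.faces))


def _humerus_mesh(spec: PhantomSpec) -> TriMesh:
    res = spec.mesh_resolution
    r_t = spec.trochlea_radius
    r_c = spec.capitellum_radius
    d = spec.inter_center_distance
    ht = TROCHLEA_HALF_WIDTH
    sh0, sh1 = ht + 2.0, d - r_c - 2.0
    pole_t = math.asin(min(1.0 / r_c, 0.5))  # last ring before the lateral pole

    bosses = [o for o in spec.osteophytes if o.attached_to == "humerus"]

    # x stations: trochlea band at full resolution, coarser shaft/neck,
    # angle-uniform sampling over the capitellar sphere, fine near bosses.
    x_parts = [
        np.arange(-ht, ht + res / 2, res),
        np.array([ht + _EDGE_EPS, sh0 - _EDGE_EPS, sh0 + _EDGE_EPS]),
        np.arange(sh0 + 1.0, sh1 - 0.5, 1.5),
        np.array([sh1 - _EDGE_EPS, sh1 + _EDGE_EPS]),
        np.arange(sh1 + 1.0, d - r_c, 1.0),
        d + r_c * np.cos(np.arange(math.pi, pole_t, -res / r_c)),
        np.array([d, d + r_c * math.sin(pole_t) * 0.0 + r_c * math.cos(pole_t)]),
    ]
    x = _dedupe(np.concatenate(x_parts))
    x = _refined_stations(
        x,
        [(o.x_mm - o.size_mm - 0.3, o.x_mm + o.size_mm + 0.3) for o in bosses],
        res / 2.5,
    )
    x = x[(x >= -ht) & (x <= d + r_c * math.cos(pole_t) + 1e-12)]

    # phi stations: uniform, refined near bosses and the articular-arc edges
    spans = []
    for o in bosses:
        w = math.asin(min(o.size_mm / r_t, 1.0)) + 0.08
        c = math.radians(o.center_angle_deg)
        spans.append((c - w, c + w))
    if spec.trochlea_arc_deg < 360:
        t0, t1 = (math.radians(t) for t in _trochlea_arc_bounds(spec))
        spans += [
            (t0 - _EDGE_EPS, t0 + _EDGE_EPS),
            (t1 - _EDGE_EPS, t1 + _EDGE_EPS),
        ]
    nphi = int(math.ceil(2 * math.pi * r_t / res))
    phi = _refined_stations(
        np.arange(nphi) * 2 * math.pi / nphi,
        [(max(lo, -2 * math.pi), hi) for lo, hi in spans],
        res / (2.5 * r_t),
    )
    phi = phi % (2 * math.pi)
    phi = _dedupe(phi)

    # radial profile
    r = np.zeros((len(x), len(phi)))
    in_troch = x <= ht + 1e-12
    if spec.trochlea_arc_deg < 360:
        t0, t1 = _trochlea_arc_bounds(spec)
        dphi_arc = np.degrees(_wrap_dphi(phi, (t0 + t1) / 2))
        on_arc = np.abs(dphi_arc) <= spec.trochlea_arc_deg / 2
        base_t = np.where(on_arc, r_t, 0.7 * r_t)
    else:
        base_t = np.full(len(phi), r_t)
    r[in_troch] = base_t[None, :]

    neck = (x > ht) & (x < d - 3.0)
    r[neck] = NECK_RADIUS
    s0, s1 = (math.radians(a) for a in HUM_SHAFT_SECTOR_DEG)
    in_shaft_x = (x >= sh0) & (x <= sh1)
    in_shaft_phi = (phi >= s0) & (phi <= s1)
    r[np.ix_(in_shaft_x, in_shaft_phi)] = spec.shaft_length

    sphere = np.sqrt(np.maximum(r_c**2 - (x - d) ** 2, 0.0))
    r = np.maximum(r, sphere[:, None])

    for o in bosses:
        boss = _boss_radial(
            r_t, o.size_mm, x - o.x_mm, _wrap_dphi(phi, o.center_angle_deg), True
        )
        valid = in_troch[:, None] & ~np.isnan(boss)
        r[valid] = np.maximum(r[valid], boss[valid])

    return _tube_mesh(x, phi, r, close_start=True, close_end=True)


def _forearm_mesh(spec: PhantomSpec) -> TriMesh:
    res = spec.mesh_resolution
    r_in = spec.cup_inner_radius
    r_out0 = r_in + CUP_WALL_THICKNESS
    hc = CUP_HALF_WIDTH
    a0, a1 = math.radians(CUP_START_DEG), math.radians(CUP_END_DEG)
    bosses = [o for o in spec.osteophytes if o.attached_to == "forearm"]

    x = np.arange(-hc, hc + res / 2, res)
    x = _refined_stations(
        x,
        [(o.x_mm - o.size_mm - 0.3, o.x_mm + o.size_mm + 0.3) for o in bosses],
        res / 2.5,
    )
    x = x[(x >= -hc) & (x <= hc + 1e-12)]
    if x[-1] < hc:
        x = np.append(x, hc)

    f0, f1 = (math.radians(a) for a in FOREARM_SHAFT_SECTOR_DEG)
    psi = _refined_stations(
        np.arange(a0, a1 + 1e-9, res / r_in),
        [
            (f0 - _EDGE_EPS, f0 + _EDGE_EPS),
            (f1 - _EDGE_EPS, f1 + _EDGE_EPS),
        ]
        + [
            (
                math.radians(o.center_angle_deg)
                - math.asin(min(o.size_mm / r_in, 1.0))
                - 0.08,
                math.radians(o.center_angle_deg)
                + math.asin(min(o.size_mm / r_in, 1.0))
                + 0.08,
            )
            for o in bosses
        ],
        res / (2.5 * r_in),
    )
    psi = psi[(psi >= a0) & (psi <= a1)]
    if psi[-1] < a1:
        psi = np.append(psi, a1)

    r_inner = np.full((len(x), len(psi)), r_in)
    for o in bosses:
        boss = _boss_radial(
            r_in, o.size_mm, x - o.x_mm,
            _wrap_dphi(psi, o.center_angle_deg), False,
        )
        valid = ~np.isnan(boss)
        r_inner[valid] = np.minimum(r_inner[valid], boss[valid])

    in_shaft = (psi >= f0) & (psi <= f1)
    r_outer_line = np.where(in_shaft, spec.shaft_length, r_out0)
    r_outer = np.tile(r_outer_line, (len(x), 1))

    nx, npsi = len(x), len(psi)
    cosp, sinp = np.cos(psi), np.sin(psi)

    def grid_verts(rr):
        return np.column_stack(
            [
                np.repeat(x, npsi),
                (rr * cosp[None, :]).ravel(),
                (rr * sinp[None, :]).ravel(),
            ]
        )

    v_in = grid_verts(r_inner)
    v_out = grid_verts(r_outer)
    verts = np.vstack([v_in, v_out])
    off = len(v_in)

    def quads(idx_a, idx_b, idx_c, idx_d):
        return np.vstack(
            [np.column_stack([idx_a, idx_b, idx_c]),
             np.column_stack([idx_b, idx_d, idx_c])]
        )

    faces = []
    ii, jj = np.meshgrid(np.arange(nx - 1), np.arange(npsi - 1), indexing="ij")
    a = (ii * npsi + jj).ravel()
    b = (ii * npsi + jj + 1).ravel()
    c = ((ii + 1) * npsi + jj).ravel()
    dd = ((ii + 1) * npsi + jj + 1).ravel()
    faces.append(quads(a, b, c, dd))                      # inner sheet
    faces.append(quads(off + a, off + c, off + b, off + dd))  # outer sheet
    # psi = a0 / a1 walls (strips along x)
    i = np.arange(nx - 1)
    faces.append(quads(i * npsi, (i + 1) * npsi, off + i * npsi, off + (i + 1) * npsi))
    j_last = npsi - 1
    faces.append(
        quads(off + i * npsi + j_last, off + (i + 1) * npsi + j_last,
              i * npsi + j_last, (i + 1) * npsi + j_last)
    )
    # x-end walls (strips along psi)
    j = np.arange(npsi - 1)
    faces.append(quads(j, off + j, j + 1, off + j + 1))
    base = (nx - 1) * npsi
    faces.append(quads(off + base + j, base + j, off + base + j + 1, base + j + 1))

    return _finalize(verts, np.vstack(faces))


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Build the phantom meshes and their analytic ground truth.

    Deterministic: the same spec yields byte-identical meshes.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    humerus = _humerus_mesh(spec)
    humerus.name = "humerus"
    forearm = _forearm_mesh(spec)
    forearm.name = "forearm"
    x_hat = np.array([1.0, 0.0, 0.0])
    tro_ring = Ring(center=np.zeros(3), radius=spec.trochlea_radius, normal=x_hat)
    cap_ring = Ring(
        center=np.array([spec.inter_center_distance, 0.0, 0.0]),
        radius=spec.capitellum_radius,
        normal=x_hat,
    )
    axis = HingeAxis(
        point=tro_ring.center,
        direction=x_hat,
        diagnostics={"source": "phantom-ground-truth"},
    )
    return Phantom(
        humerus_mesh=humerus,
        forearm_mesh=forearm,
        true_axis=axis,
        true_rings=(tro_ring, cap_ring),
        spec=spec,
    )


# -- landmark sampling -----------------------------------------------------

#: Minimum circumferential separation between sampled landmarks (deg);
#: keeps the circumcircle well-conditioned under noise.
MIN_LANDMARK_SEPARATION_DEG = 20.0


def _ring_exclusions(spec: PhantomSpec) -> list[tuple[float, float]]:
    """Angular zones (deg) on the trochlear ring to avoid when landmarking:
    osteophyte footprints and the non-articular recess.  Mirrors the clinical
    guidance of plotting points away from spurs and erosions."""
    zones = []
    for o in spec.osteophytes:
        if o.attached_to != "humerus":
            continue
        w = math.degrees(math.asin(min(o.size_mm / spec.trochlea_radius, 1.0))) + 5.0
        zones.append((o.center_angle_deg - w, o.center_angle_deg + w))
    return zones


def sample_landmarks(
    phantom: Phantom, noise_sd: float = 0.0, seed: int = 0
) -> LandmarkSet:
    """Three seeded points per articular ring, optionally noise-perturbed.

    Points are drawn at random circumferential stations on each true ring
    (pairwise separation >= 20 deg, avoiding osteophyte footprints and any
    non-articular recess), then perturbed by isotropic Gaussian noise of
    standard deviation ``noise_sd`` (mm).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    spec = phantom.spec

    def allowed(angle: float, zones) -> bool:
        for lo, hi in zones:
            if lo - 1e-9 <= _norm_angle(angle, (lo + hi) / 2) <= hi + 1e-9:
                return False
        return True

    def draw_angles(zones, lo=0.0, hi=360.0, circular=True):
        for _ in range(10_000):
            angles = np.sort(rng.uniform(lo, hi, size=3))
            gaps = np.diff(angles)
            wrap = (angles[0] + (360.0 if circular else hi - lo)) - angles[-1]
            if min(gaps.min(initial=360.0), wrap) < MIN_LANDMARK_SEPARATION_DEG:
                continue
            if all(allowed(a, zones) for a in angles):
                return angles
        raise PhantomSpecError("could not place landmarks outside exclusion zones")

    if spec.trochlea_arc_deg < 360:
        t0, t1 = _trochlea_arc_bounds(spec)
        tro_angles = draw_angles(
            _ring_exclusions(spec), lo=t0 + 5.0, hi=t1 - 5.0, circular=False
        )
    else:
        tro_angles = draw_angles(_ring_exclusions(spec))
    cap_angles = draw_angles([])

    def on_ring(ring: Ring, angles_deg: np.ndarray) -> np.ndarray:
        a = np.radians(angles_deg)
        return ring.center + ring.radius * np.column_stack(
            [np.zeros_like(a), np.cos(a), np.sin(a)]
        )

    tro = on_ring(phantom.true_rings[0], tro_angles)
    cap = on_ring(phantom.true_rings[1], cap_angles)
    if noise_sd > 0:
        tro = tro + rng.normal(0.0, noise_sd, size=tro.shape)
        cap = cap + rng.normal(0.0, noise_sd, size=cap.shape)
    return LandmarkSet(tro, cap, source=f"phantom-seed{seed}-sd{noise_sd}")
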