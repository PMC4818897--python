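"""Parity ray-casting kernels shared by voxelization and point containment.

Rays are cast along +z through a lattice of column centers (voxelization) or
through arbitrary query points (containment).  A point is inside a closed,
consistently wound surface iff an odd number of triangle crossings lies below
it.  Coverage of a column by a projected triangle uses the standard
half-open (top-left) boundary rule so that a crossing on a shared edge is
counted exactly once; for arbitrary query points the whole scene is first
rotated by a tiny fixed angle to break exact edge/vertex alignments.
"""

from __future__ import annotations

import numpy as np

# Fixed scene jitter (radians) used by points_in_mesh; rigid, so containment
# itself is unchanged - only degenerate ray/edge alignments are broken.
_JITTER_ROTVEC = np.array([1.37e-5, 2.91e-5, -2.13e-5])


def _oriented_projected(tri_xyz: np.ndarray):
    """Orient triangles CCW in the xy-projection; drop projected slivers.

    Returns (tri_xyz_oriented, keep_mask) where kept triangles have strictly
    positive projected area.
    """
    p0, p1, p2 = tri_xyz[:, 0], tri_xyz[:, 1], tri_xyz[:, 2]
    area2 = (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1]) - (
        p1[:, 1] - p0[:, 1]
    ) * (p2[:, 0] - p0[:, 0])
    flip = area2 < 0
    out = tri_xyz.copy()
    out[flip, 1], out[flip, 2] = tri_xyz[flip, 2], tri_xyz[flip, 1]
    keep = area2 != 0.0
    return out[keep]


def _edge_inside(ax, ay, bx, by, px, py):
    """Half-open edge test: point strictly left of a->b, or on a top-left edge."""
    e = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    dy = by - ay
    dx = bx - ax
    topleft = (dy < 0) | ((dy == 0) & (dx < 0))
    return (e > 0) | ((e == 0) & topleft)


def _crossing_z(tri, px, py):
    """z of the triangle's plane above (px, py); tri is (n,3,3) CCW in xy."""
    p0 = tri[:, 0]
    e1 = tri[:, 1] - p0
    e2 = tri[:, 2] - p0
    n = np.cross(e1, e2)  # n[:,2] > 0 by orientation
    return p0[:, 2] + (
        -n[:, 0] * (px - p0[:, 0]) - n[:, 1] * (py - p0[:, 1])
    ) / n[:, 2]


def occupancy_grid(
    vertices: np.ndarray,
    faces: np.ndarray,
    origin: np.ndarray,
    shape: tuple[int, int, int],
    voxel_size: float,
) -> np.ndarray:
    """Boolean occupancy of cell centers inside a closed surface.

    Cell centers sit at ``origin + (index + 0.5) * voxel_size``.  Crossings
    outside the grid's z-range are still counted so that a grid covering only
    part of the mesh yields correct parity.
    """
    nx, ny, nz = (int(s) for s in shape)
    v = float(voxel_size)
    ox, oy, oz = (float(o) for o in np.asarray(origin, dtype=float))
    occ_flip = np.zeros((nx, ny, nz + 1), dtype=np.int64)
    if len(faces) == 0:
        return np.zeros((nx, ny, nz), dtype=bool)

    tri = _oriented_projected(np.asarray(vertices, float)[np.asarray(faces)])
    if len(tri) == 0:
        return np.zeros((nx, ny, nz), dtype=bool)

    # Candidate column index range per triangle, clipped to the grid.
    txy = tri[:, :, :2]
    xmin = txy[:, :, 0].min(axis=1)
    xmax = txy[:, :, 0].max(axis=1)
    ymin = txy[:, :, 1].min(axis=1)
    ymax = txy[:, :, 1].max(axis=1)
    i0 = np.clip(np.ceil((xmin - ox) / v - 0.5).astype(np.int64), 0, nx)
    i1 = np.clip(np.floor((xmax - ox) / v - 0.5).astype(np.int64) + 1, 0, nx)
    j0 = np.clip(np.ceil((ymin - oy) / v - 0.5).astype(np.int64), 0, ny)
    j1 = np.clip(np.floor((ymax - oy) / v - 0.5).astype(np.int64) + 1, 0, ny)
    wx = np.maximum(i1 - i0, 0)
    wy = np.maximum(j1 - j0, 0)
    counts = wx * wy
    keep = counts > 0
    tri, i0, j0, wx, wy, counts = (
        tri[keep], i0[keep], j0[keep], wx[keep], wy[keep], counts[keep],
    )
    if len(tri) == 0:
        return np.zeros((nx, ny, nz), dtype=bool)

    total = int(counts.sum())
    tid = np.repeat(np.arange(len(tri)), counts)
    local = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    ci = i0[tid] + local // wy[tid]
    cj = j0[tid] + local % wy[tid]
    px = ox + (ci + 0.5) * v
    py = oy + (cj + 0.5) * v

    t = tri[tid]
    inside = (
        _edge_inside(t[:, 0, 0], t[:, 0, 1], t[:, 1, 0], t[:, 1, 1], px, py)
        & _edge_inside(t[:, 1, 0], t[:, 1, 1], t[:, 2, 0], t[:, 2, 1], px, py)
        & _edge_inside(t[:, 2, 0], t[:, 2, 1], t[:, 0, 0], t[:, 0, 1], px, py)
    )
    if not inside.any():
        return np.zeros((nx, ny, nz), dtype=bool)
    t, ci, cj, px, py = t[inside], ci[inside], cj[inside], px[inside], py[inside]
    zc = _crossing_z(t, px, py)
    # index of the first cell center strictly above the crossing
    k = np.clip(np.ceil((zc - oz) / v - 0.5).astype(np.int64), 0, nz)
    np.add.at(occ_flip, (ci, cj, k), 1)
    return (np.cumsum(occ_flip[:, :, :nz], axis=2) % 2).astype(bool)


def points_inside(
    vertices: np.ndarray,
    faces: np.ndarray,
    points: np.ndarray,
    chunk: int = 4_000_000,
) -> np.ndarray:
    """Parity containment test for arbitrary points (ray along +z, jittered)."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return np.zeros(0, dtype=bool)
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(_JITTER_ROTVEC).as_matrix()
    verts = np.asarray(vertices, float) @ rot.T
    pts = points @ rot.T
    tri = _oriented_projected(verts[np.asarray(faces)])
    if len(tri) == 0:
        return np.zeros(len(points), dtype=bool)

    crossings = np.zeros(len(pts), dtype=np.int64)
    # Chunk the points x triangles product to bound memory.
    tchunk = max(1, chunk // max(len(pts), 1))
    for s in range(0, len(tri), tchunk):
        t = tri[s : s + tchunk]
        px = pts[:, None, 0]
        py = pts[:, None, 1]
        inside = (
            _edge_inside(t[None, :, 0, 0], t[None, :, 0, 1],
                         t[None, :, 1, 0], t[None, :, 1, 1], px, py)
            & _edge_inside(t[None, :, 1, 0], t[None, :, 1, 1],
                           t[None, :, 2, 0], t[None, :, 2, 1], px, py)
            & _edge_inside(t[None, :, 2, 0], t[None, :, 2, 1],
                           t[None, :, 0, 0], t[None, :, 0, 1], px, py)
        )
        pi, ti = np.nonzero(inside)
        if len(pi):
            zc = _crossing_z(t[ti], pts[pi, 0], pts[pi, 1])
            # boundary rule: a crossing at the point's own z counts (inside)
            above = zc >= pts[pi, 2]
            np.add.at(crossings, pi[above], 1)
    return crossings % 2 == 1
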