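"""Triangulated surface model, STL/PLY I/O, containment and voxelization.

All coordinates are millimetres.  CT exports carry no unit metadata, so
meshes are taken as mm as-is (the CLI exposes a ``--units-scale`` override).
STL and PLY parsing/writing are delegated to :mod:`trimesh`; the geometric
predicates (signed volume, parity ray containment, center-containment
voxelization) are implemented here because the rest of the package depends
on their exact semantics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import trimesh as _tm

from . import _raster
from .errors import (
    EmptyMeshError,
    MeshFormatError,
    NotWatertightError,
    ResourceLimitError,
)

#: Vertices closer than this (mm) are merged on load; far below CT feature size.
WELD_TOLERANCE = 1e-6

#: Hard cap on voxel-grid cells; beyond this a larger voxel_size is required.
MAX_VOXEL_CELLS = 150_000_000


@dataclass
class TriMesh:
    """A triangulated surface in mm: (n,3) float vertices, (m,3) int faces.

    Faces are counter-clockwise when viewed from outside, so a watertight
    mesh has positive enclosed volume.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be an (m, 3) array")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise MeshFormatError("face index exceeds vertex count")

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        """(2,3) axis-aligned bounding box: [min; max]."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def to_trimesh(self) -> _tm.Trimesh:
        return _tm.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, m: _tm.Trimesh, name: str = "") -> "TriMesh":
        return cls(np.asarray(m.vertices), np.asarray(m.faces), name=name)

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def open_edge_count(self) -> int:
        m = self.to_trimesh()
        edges = m.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.sum(counts != 2))

    def require_watertight(self) -> None:
        if not self.is_watertight:
            raise NotWatertightError(self.open_edge_count(), self.name or "mesh")

    def validated(self) -> "TriMesh":
        """Drop zero-area faces (exact duplicates of a vertex in a face)."""
        v = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )
        return TriMesh(self.vertices, self.faces[areas > 0.0], name=self.name)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriMesh":
        """Rigidly transformed copy: x -> R x + t. Topology untouched."""
        v = self.vertices @ np.asarray(rotation, float).T + np.asarray(
            translation, float
        )
        return TriMesh(v, self.faces.copy(), name=self.name)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), name=self.name)


@dataclass
class VoxelGrid:
    """Axis-aligned boolean occupancy lattice; centers at origin+(i+0.5)*size."""

    origin: np.ndarray
    voxel_size: float
    shape: tuple[int, int, int]
    occupancy: np.ndarray = field(repr=False)

    @property
    def occupied_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume(self) -> float:
        """Occupied-cell count x voxel_size^3 (mm^3)."""
        return self.occupied_count * self.voxel_size**3

    def cell_centers(self) -> np.ndarray:
        """(k,3) coordinates of occupied cell centers."""
        idx = np.argwhere(self.occupancy)
        return self.origin + (idx + 0.5) * self.voxel_size


# -- I/O -------------------------------------------------------------------


def read_stl(path: str | os.PathLike, units_scale: float = 1.0) -> TriMesh:
    """Read a binary or ASCII STL file, welding duplicate vertices.

    STL stores one triangle at a time with repeated corner coordinates;
    vertices within :data:`WELD_TOLERANCE` are merged so the surface has
    shared topology.  Face count is preserved.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        m = _tm.load_mesh(path, file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad files
        raise MeshFormatError(f"cannot parse STL file {path!r}: {exc}") from exc
    if not isinstance(m, _tm.Trimesh) or len(m.faces) == 0:
        raise EmptyMeshError(f"no triangles in {path!r}")
    m.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=None)
    mesh = TriMesh.from_trimesh(m, name=os.path.splitext(os.path.basename(path))[0])
    if units_scale != 1.0:
        mesh.vertices = mesh.vertices * float(units_scale)
    return mesh.validated()


def write_stl(mesh: TriMesh, path: str | os.PathLike, ascii: bool = False) -> None:
    """Write STL (binary by default)."""
    m = mesh.to_trimesh()
    path = os.fspath(path)
    if ascii:
        with open(path, "w") as fh:
            fh.write(_tm.exchange.stl.export_stl_ascii(m))
    else:
        m.export(path, file_type="stl")


def write_ply(
    mesh: TriMesh,
    path: str | os.PathLike,
    face_mask: np.ndarray | None = None,
    highlight_rgb: tuple[int, int, int] = (255, 0, 0),
    base_rgb: tuple[int, int, int] = (200, 200, 200),
) -> None:
    """Write PLY with per-face 8-bit RGB; masked faces get the highlight color.

    Used to flag impinging faces (red by convention).
    """
    colors = np.tile(np.asarray(base_rgb, dtype=np.uint8), (len(mesh.faces), 1))
    if face_mask is not None:
        mask = np.asarray(face_mask, dtype=bool)
        colors[mask] = np.asarray(highlight_rgb, dtype=np.uint8)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(mesh.vertices)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
        "end_header",
    ]
    lines.extend(f"{v[0]:.8f} {v[1]:.8f} {v[2]:.8f}" for v in mesh.vertices)
    lines.extend(
        f"3 {f[0]} {f[1]} {f[2]} {c[0]} {c[1]} {c[2]}"
        for f, c in zip(mesh.faces, colors)
    )
    with open(os.fspath(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


# -- geometric predicates --------------------------------------------------


def mesh_volume(mesh: TriMesh, return_orientation: bool = False):
    """Enclosed volume (mm^3) of a watertight mesh by the divergence theorem.

    Returns the absolute volume; with ``return_orientation=True`` also
    returns ``"outward"`` or ``"inward"`` for the face winding.
    """
    mesh.require_watertight()
    v = mesh.vertices[mesh.faces]
    signed = float(np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2])) / 6.0)
    orientation = "outward" if signed >= 0 else "inward"
    if return_orientation:
        return abs(signed), orientation
    return abs(signed)


def points_in_mesh(mesh: TriMesh, points: np.ndarray) -> np.ndarray:
    """True for each point strictly inside the watertight mesh.

    Parity ray casting with a fixed, slightly jittered ray direction;
    points on the surface resolve within one float tolerance of inside.
    """
    mesh.require_watertight()
    return _raster.points_inside(mesh.vertices, mesh.faces, points)


def voxelize(mesh: TriMesh, voxel_size: float, pad_voxels: int = 1) -> VoxelGrid:
    """Center-containment voxelization on a grid covering the padded bbox.

    A cell is occupied iff its center lies inside the mesh; the grid is
    aligned to the bounding-box minimum and padded by ``pad_voxels`` cells.
    """
    if voxel_size <= 0:
        raise ValueError(f"voxel_size must be positive, got {voxel_size}")
    mesh.require_watertight()
    v = float(voxel_size)
    lo, hi = mesh.bounds
    origin = lo - pad_voxels * v
    shape = tuple(
        int(np.ceil((hi[i] - origin[i]) / v)) + pad_voxels for i in range(3)
    )
    ncells = int(np.prod(shape))
    if ncells > MAX_VOXEL_CELLS:
        raise ResourceLimitError(
            f"grid of {ncells} cells exceeds budget {MAX_VOXEL_CELLS}; "
            f"increase voxel_size (got {v} mm)"
        )
    occ = _raster.occupancy_grid(mesh.vertices, mesh.faces, origin, shape, v)
    return VoxelGrid(origin=origin, voxel_size=v, shape=shape, occupancy=occ)


def occupancy_on_grid(
    mesh: TriMesh, origin: np.ndarray, shape: tuple[int, int, int], voxel_size: float
) -> np.ndarray:
    """Center-containment occupancy of an arbitrary externally defined grid."""
    mesh.require_watertight()
    return _raster.occupancy_grid(
        mesh.vertices, mesh.faces, np.asarray(origin, float), shape, float(voxel_size)
    )
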