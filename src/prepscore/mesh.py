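"""Triangulated surface meshes: STL I/O, validation, masking, closest-surface queries.

All coordinates are assumed to be in millimetres (STL itself is unitless;
dental CAD/CAM scanners export metric meshes and every clinical threshold
used downstream — 0.25 mm error unit, 1.25/1.50 mm ideal dimensions — is
metric).

Closest-point queries are point-to-*surface* (exact point-to-triangle
projection), not point-to-vertex: on coarse scans a vertex-only distance
systematically overestimates the deviation map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
import trimesh.triangles
from scipy.spatial import cKDTree

__all__ = [
    "Mesh",
    "VertexMask",
    "SurfaceQueryResult",
    "BoxRegion",
    "CylinderRegion",
    "MeshFormatError",
    "MeshValidationError",
    "read_stl",
    "write_stl",
    "closest_surface_point",
    "closest_surface_points",
    "mask_by_region",
    "SurfaceIndex",
]

#: Vertices closer than this (mm) are welded into one on load.
WELD_TOLERANCE = 1e-6


class MeshFormatError(ValueError):
    """Raised when an STL file cannot be parsed."""


class MeshValidationError(ValueError):
    """Raised when mesh data violates a structural invariant."""


@dataclass
class Mesh:
    """A triangulated surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    name : free-text label
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise MeshValidationError("mesh is empty")
        if not np.isfinite(self.vertices).all():
            raise MeshValidationError("non-finite vertex coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshValidationError("face index out of range")
        degenerate = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if degenerate.any():
            raise MeshValidationError(
                f"{int(degenerate.sum())} degenerate face(s) with repeated vertex indices"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        """Unit normals per face from the winding order (right-hand rule)."""
        t = self.triangles
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        norm = np.linalg.norm(n, axis=1)
        norm[norm == 0] = 1.0
        return n / norm[:, None]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def copy(self) -> "Mesh":
        return Mesh(self.vertices.copy(), self.faces.copy(), self.name)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass
class VertexMask:
    """Boolean inclusion flag per vertex of a specific mesh."""

    included: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        if self.included.ndim != 1:
            raise MeshValidationError("mask must be a 1-D boolean array")

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def validate_for(self, mesh: Mesh, minimum: int = 3) -> None:
        if len(self.included) != mesh.n_vertices:
            raise MeshValidationError(
                f"mask length {len(self.included)} != vertex count {mesh.n_vertices}"
            )
        if self.n_included < minimum:
            raise MeshValidationError(
                f"mask leaves {self.n_included} vertices; at least {minimum} required"
            )

    @staticmethod
    def all_of(mesh: Mesh, description: str = "all vertices") -> "VertexMask":
        return VertexMask(np.ones(mesh.n_vertices, dtype=bool), description)


@dataclass(frozen=True)
class SurfaceQueryResult:
    """Closest point on a surface to a query point."""

    closest_point: np.ndarray
    distance: float
    face_index: int


@dataclass(frozen=True)
class BoxRegion:
    """Axis-aligned box, used e.g. to exclude the cavity zone from alignment."""

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        return np.all((points >= lo) & (points <= hi), axis=1)


@dataclass(frozen=True)
class CylinderRegion:
    """Infinite vertical cylinder (radial zone about the occlusal axis)."""

    center_xy: tuple[float, float]
    radius: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center_xy, dtype=float)
        return np.linalg.norm(points[:, :2] - c, axis=1) <= self.radius


def read_stl(path: str | Path) -> Mesh:
    """Read a binary or ASCII STL file into a validated, vertex-welded :class:`Mesh`.

    STL stores independent facets; duplicated corner vertices are merged so
    that faces index a shared vertex list (required by vertex masks and the
    deviation map).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tm = trimesh.load_mesh(str(path), file_type="stl", process=True)
    except Exception as exc:  # trimesh raises a mixture of exception types
        raise MeshFormatError(f"cannot parse STL file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.vertices) == 0 or len(tm.faces) == 0:
        raise MeshValidationError(f"STL file {path} contains no triangles")
    tm.merge_vertices(digits_vertex=6)  # weld at 1e-6 mm
    return Mesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces), name=path.stem)


def write_stl(mesh: Mesh, path: str | Path, dialect: str = "binary") -> None:
    """Write a mesh as STL; ``dialect`` is ``"binary"`` or ``"ascii"``."""
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    tm = mesh.to_trimesh()
    data = trimesh.exchange.stl.export_stl(tm) if dialect == "binary" else \
        trimesh.exchange.stl.export_stl_ascii(tm).encode()
    Path(path).write_bytes(data)


class SurfaceIndex:
    """Exact accelerated closest-point-on-surface queries.

    A KD-tree over triangle centroids supplies an upper bound (distance to
    the nearest centroid's triangle); any triangle containing a closer point
    must have its centroid within ``upper_bound + max_circumradius`` of the
    query, so a ball query yields a provably sufficient candidate set and the
    result equals the exhaustive minimum over all triangles.
    """

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self._tri = mesh.triangles
        self._centroids = self._tri.mean(axis=1)
        radii = np.linalg.norm(self._tri - self._centroids[:, None, :], axis=2).max(axis=1)
        self._rmax = float(radii.max())
        self._tree = cKDTree(self._centroids)
        self._normals = mesh.face_normals()

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest_points, distances, face_indices) for (n, 3) queries."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        # upper bound: exact distance to the triangle whose centroid is nearest
        _, seed_face = self._tree.query(points)
        seed_cp = trimesh.triangles.closest_point(self._tri[seed_face], points)
        ub = np.linalg.norm(points - seed_cp, axis=1)

        groups = self._tree.query_ball_point(points, ub + self._rmax + 1e-12)
        counts = np.array([len(g) for g in groups])
        face_idx = np.fromiter(
            (f for g in groups for f in g), dtype=np.int64, count=int(counts.sum())
        )
        pt_idx = np.repeat(np.arange(n), counts)
        cps = trimesh.triangles.closest_point(self._tri[face_idx], points[pt_idx])
        d = np.linalg.norm(points[pt_idx] - cps, axis=1)

        # groupwise argmin (pt_idx is sorted)
        order = np.lexsort((d, pt_idx))
        first = np.zeros(n, dtype=np.int64)
        first[1:] = np.cumsum(counts)[:-1]
        best = order[first]
        return cps[best], d[best], face_idx[best]

    def signed_distances(self, points: np.ndarray) -> np.ndarray:
        """Distances signed by the nearest face's normal: negative below the
        surface (inside the solid, assuming outward/occlusal-up winding)."""
        cp, d, fi = self.query(points)
        side = np.einsum("ij,ij->i", np.atleast_2d(points) - cp, self._normals[fi])
        return np.where(side >= 0, d, -d)


def closest_surface_points(mesh: Mesh, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batch closest-surface query; see :class:`SurfaceIndex`."""
    return SurfaceIndex(mesh).query(points)


def closest_surface_point(mesh: Mesh, query) -> SurfaceQueryResult:
    """Globally closest point on ``mesh`` to a single 3-D query point."""
    cp, d, fi = SurfaceIndex(mesh).query(np.asarray(query, dtype=float)[None, :])
    return SurfaceQueryResult(cp[0], float(d[0]), int(fi[0]))


def mask_by_region(
    mesh: Mesh,
    region: BoxRegion | CylinderRegion,
    description: str = "",
    minimum: int = 3,
) -> VertexMask:
    """Mask that *excludes* every vertex inside ``region`` (e.g. the occlusal
    cavity zone, which must not drive the alignment)."""
    inside = region.contains(mesh.vertices)
    mask = VertexMask(~inside, description or f"exclude {region!r}")
    mask.validate_for(mesh, minimum=minimum)
    return mask
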