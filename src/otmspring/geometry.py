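"""Triangular surface meshes, rigid-body poses and oriented planes.

All lengths are millimetres. A :class:`TriMesh` is a plain vertex/face
container with lazily computed per-face area, outward unit normal and
centroid; file I/O (STL, OBJ, PLY) is delegated to :mod:`trimesh`.
A :class:`RigidPose` is an element of SE(3) — a proper rotation plus a
translation — and is how the tooth's six degrees of freedom are carried
through the solver.  A :class:`Plane` models the gingival line as a flat
boundary with its unit normal pointing toward the occlusal side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TriMesh",
    "RigidPose",
    "Plane",
    "load_mesh",
    "save_mesh",
    "apply_pose",
    "signed_distance",
    "rotation_about_axis",
]

_AREA_EPS = 1e-12


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed or contains degenerate faces."""


@dataclass
class TriMesh:
    """Triangular surface mesh (vertices in mm, faces as index triplets)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be an (m, 3) array of vertex indices")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshFormatError(
                f"face index out of range (max index {self.faces.max()}, "
                f"{len(self.vertices)} vertices)"
            )
        areas = self.face_areas
        bad = np.flatnonzero(areas <= _AREA_EPS)
        if bad.size:
            raise MeshFormatError(f"degenerate (zero-area) face at index {bad[0]}")

    # -- derived per-face quantities ------------------------------------
    @property
    def _tri(self) -> np.ndarray:
        return self.vertices[self.faces]  # (m, 3, 3)

    @property
    def face_cross(self) -> np.ndarray:
        t = self._tri
        return np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])

    @property
    def face_areas(self) -> np.ndarray:
        """Per-face area [mm^2] from the cross-product formula."""
        return 0.5 * np.linalg.norm(self.face_cross, axis=1)

    @property
    def face_normals(self) -> np.ndarray:
        """Per-face unit normals following the winding order."""
        c = self.face_cross
        return c / np.linalg.norm(c, axis=1, keepdims=True)

    @property
    def face_centroids(self) -> np.ndarray:
        """Per-face centroid = mean of the three vertices [mm]."""
        return self._tri.mean(axis=1)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def transformed(self, pose: "RigidPose") -> "TriMesh":
        return TriMesh(pose.apply(self.vertices), self.faces.copy())

    def center(self) -> np.ndarray:
        """Mean vertex position; used for outward-orientation checks."""
        return self.vertices.mean(axis=0)


def face_properties(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (areas, outward unit normals, centroids) per face."""
    return mesh.face_areas, mesh.face_normals, mesh.face_centroids


def load_mesh(path: str | Path, file_format: str | None = None) -> TriMesh:
    """Load an STL/OBJ/PLY surface mesh (coordinates in mm).

    Quads and polygons are triangulated by trimesh; degenerate faces are
    rejected with :class:`MeshFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    try:
        tm = _trimesh.load_mesh(str(path), file_type=file_format, process=False)
    except Exception as exc:  # trimesh raises many concrete types
        raise MeshFormatError(f"could not parse mesh file {path}: {exc}") from exc
    if isinstance(tm, _trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshFormatError(f"no geometry in {path}")
        tm = _trimesh.util.concatenate(geoms)
    return TriMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))


def save_mesh(mesh: TriMesh, path: str | Path) -> None:
    """Write the mesh in the format implied by the file extension."""
    mesh.to_trimesh().export(str(path))


@dataclass
class RigidPose:
    """Proper rigid transform p -> R p + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if self.rotation.shape != (3, 3) or err > 1e-9:
            raise ValueError(f"rotation is not orthonormal (max |R R^T - I| = {err:.3g})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Pose equivalent to applying ``other`` first, then ``self``."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidPose":
        rt = self.rotation.T
        return RigidPose(rt, -rt @ self.translation)


def apply_pose(pose: RigidPose, points: np.ndarray) -> np.ndarray:
    """Apply ``pose`` to one point or an (n, 3) array of points."""
    return pose.apply(points)


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues formula via scipy)."""
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(angle_rad * axis).as_matrix()


@dataclass
class Plane:
    """Oriented plane; ``normal`` points toward the occlusal side."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError("plane normal must be non-zero")
        self.normal = n / norm


def signed_distance(plane: Plane, points: np.ndarray) -> np.ndarray | float:
    """Signed distance [mm]; positive on the side the normal points to."""
    pts = np.asarray(points, dtype=float)
    d = (pts - plane.point) @ plane.normal
    return float(d) if pts.ndim == 1 else d


#: Canonical gingival plane: z = 0, occlusal side is -z.
DEFAULT_GINGIVAL_PLANE = Plane(point=np.zeros(3), normal=np.array([0.0, 0.0, -1.0]))
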