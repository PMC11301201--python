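"""Periodontal-ligament spring-block field.

The PDL is discretized into one spring block per root-surface face. Each
block connects the face centroid (tooth side, moving with the rigid tooth)
to a bone anchor one ligament thickness away along the outward normal, and
carries a linear (normal) spring and a shear spring. Stiffnesses are
normalized by the face area: k_n = E a / l0, k_s = G a / l0, which makes
the total reaction for a given displacement independent of mesh
resolution.

Deformation of a block under a tooth pose, with d = anchor - world tooth
point and n the rest axis (outward normal at rest):

* stretch       l - l0, with l = |d|
* shear ratio   tan(theta) = |d - (d.n) n| / max(d.n, eps)
* normal stress sigma = E (l - l0) / l0
* shear stress  tau   = G tan(theta)

Compression is limited: a stiff quadratic barrier activates once the
normal projection d.n falls below a fraction c of the rest length,
modelling the incompressible floor of the ligament. Blocks whose
tooth-side point crosses the gingival plane occlusally are removed
permanently (the fibre is torn, as in eruption/extrusion).

Stresses are reported in kPa; stiffness/energy stay in N, mm, N*mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import Plane, RigidPose, TriMesh, signed_distance
from .stress import von_mises

__all__ = [
    "PDLParams",
    "SpringField",
    "SpringStates",
    "build_field",
    "compute_state",
    "compression_barrier",
    "prune_exceeding",
]

#: guard in the tan(theta) denominator at extreme compression [mm]
TAN_EPS = 1e-9

MPA_TO_KPA = 1000.0


@dataclass(frozen=True)
class PDLParams:
    """Material and constraint parameters of the ligament.

    ``young_modulus`` [MPa], ``poisson_ratio``, and ``thickness`` [mm]
    default to the literature values 0.68 MPa, 0.45 and 0.265 mm.
    ``compression_limit_fraction`` c is the floor of the normal projection
    as a fraction of the rest length; ``barrier_multiplier`` scales the
    barrier stiffness relative to the block's own k_n.
    """

    young_modulus: float = 0.68
    poisson_ratio: float = 0.45
    thickness: float = 0.265
    compression_limit_fraction: float = 0.25
    barrier_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("young_modulus must be > 0")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must be in [0, 0.5)")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if not (0.0 < self.compression_limit_fraction < 1.0):
            raise ValueError("compression_limit_fraction must be in (0, 1)")
        if self.barrier_multiplier <= 0:
            raise ValueError("barrier_multiplier must be > 0")

    @property
    def shear_modulus(self) -> float:
        """G = E / (2 (1 + nu)) [MPa]; derived, never stored."""
        return self.young_modulus / (2.0 * (1.0 + self.poisson_ratio))


@dataclass
class SpringField:
    """Vectorized collection of PDL spring blocks.

    ``tooth_points``/``normals`` are in the tooth body frame (= the world
    frame at build time, when the pose is the identity); ``bone_anchors``
    and ``rest_axes`` live in the world frame and are what remodeling
    updates. ``active`` is a permanence flag: once a block is pruned it
    never reactivates.
    """

    rest_length: float
    tooth_points: np.ndarray   # (n, 3) body frame
    normals: np.ndarray        # (n, 3) body frame, outward at build
    bone_anchors: np.ndarray   # (n, 3) world frame
    rest_axes: np.ndarray      # (n, 3) world frame, unit
    areas: np.ndarray          # (n,)  mm^2
    k_normal: np.ndarray       # (n,)  N/mm
    k_shear: np.ndarray        # (n,)  N/mm
    active: np.ndarray         # (n,)  bool
    face_indices: np.ndarray   # (n,)  index into the source mesh's faces
    rotation_center: np.ndarray  # (3,) reference point for pose rotations

    @property
    def n_blocks(self) -> int:
        return len(self.areas)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def world_tooth_points(self, pose: RigidPose) -> np.ndarray:
        return self.tooth_points @ pose.rotation.T + pose.translation

    def world_normals(self, pose: RigidPose) -> np.ndarray:
        return self.normals @ pose.rotation.T

    def copy(self) -> "SpringField":
        return SpringField(
            self.rest_length,
            self.tooth_points.copy(), self.normals.copy(),
            self.bone_anchors.copy(), self.rest_axes.copy(),
            self.areas.copy(), self.k_normal.copy(), self.k_shear.copy(),
            self.active.copy(), self.face_indices.copy(),
            self.rotation_center.copy(),
        )

    def to_csv(self, path: str | Path) -> None:
        """Dump block geometry/state flags for debugging and fixtures."""
        import pandas as pd

        df = pd.DataFrame({
            "block": np.arange(self.n_blocks),
            "face": self.face_indices,
            "tx": self.tooth_points[:, 0], "ty": self.tooth_points[:, 1],
            "tz": self.tooth_points[:, 2],
            "ax": self.bone_anchors[:, 0], "ay": self.bone_anchors[:, 1],
            "az": self.bone_anchors[:, 2],
            "area_mm2": self.areas,
            "active": self.active.astype(int),
        })
        df.to_csv(path, index=False)


@dataclass
class SpringStates:
    """Per-active-block deformation and stress state (arrays align with
    ``block_indices``). Stresses in kPa, lengths in mm."""

    block_indices: np.ndarray
    length: np.ndarray
    normal_projection: np.ndarray
    tan_theta: np.ndarray
    sigma: np.ndarray
    tau: np.ndarray
    von_mises: np.ndarray
    areas: np.ndarray

    @property
    def strain(self) -> np.ndarray:
        return self.sigma / self.sigma_scale

    # kPa per unit strain; set in compute_state
    sigma_scale: float = 680.0


def build_field(
    mesh: TriMesh,
    gingival_plane: Plane,
    params: PDLParams,
    face_subset: np.ndarray | None = None,
) -> SpringField:
    """Construct one spring block per face strictly apical to the plane.

    The mesh must be in its rest pose (identity). Anchors sit one
    ligament thickness outside the surface along each face normal.
    ``face_subset`` restricts candidate faces to the anatomical root
    surface (the ligament attaches to cementum, not enamel) — without it
    a tilted, partially erupted tooth would grow springs on whatever part
    of the crown dips below the gingival plane.
    """
    centroids = mesh.face_centroids
    sd = signed_distance(gingival_plane, centroids)
    apical = np.flatnonzero(sd < 0)
    if face_subset is not None:
        apical = np.intersect1d(apical, np.asarray(face_subset, dtype=np.int64))
    if apical.size == 0:
        raise ValueError("tooth entirely coronal to gingival plane: no PDL faces")
    l0 = params.thickness
    normals = mesh.face_normals[apical]
    pts = centroids[apical]
    areas = mesh.face_areas[apical]
    return SpringField(
        rest_length=l0,
        tooth_points=pts.copy(),
        normals=normals.copy(),
        bone_anchors=pts + l0 * normals,
        rest_axes=normals.copy(),
        areas=areas,
        k_normal=params.young_modulus * areas / l0,
        k_shear=params.shear_modulus * areas / l0,
        active=np.ones(apical.size, dtype=bool),
        face_indices=apical,
        rotation_center=pts.mean(axis=0),
    )


def _decompose(field: SpringField, pose: RigidPose, mask: np.ndarray):
    """Geometric deformation of the masked blocks under ``pose``."""
    x = field.tooth_points[mask] @ pose.rotation.T + pose.translation
    d = field.bone_anchors[mask] - x
    n = field.rest_axes[mask]
    length = np.linalg.norm(d, axis=1)
    proj = np.einsum("ij,ij->i", d, n)
    tvec = d - proj[:, None] * n
    s = np.linalg.norm(tvec, axis=1)
    return x, d, n, length, proj, tvec, s


def compute_state(field: SpringField, pose: RigidPose, params: PDLParams) -> SpringStates:
    """Evaluate deformation and stress of every active block (kPa)."""
    mask = field.active
    _, _, _, length, proj, _, s = _decompose(field, pose, mask)
    l0 = field.rest_length
    p_eff = np.maximum(proj, TAN_EPS)
    tan_theta = s / p_eff
    e_kpa = params.young_modulus * MPA_TO_KPA
    g_kpa = params.shear_modulus * MPA_TO_KPA
    sigma = e_kpa * (length - l0) / l0
    tau = g_kpa * tan_theta
    vm = von_mises(sigma, tau)
    return SpringStates(
        block_indices=np.flatnonzero(mask),
        length=length,
        normal_projection=proj,
        tan_theta=tan_theta,
        sigma=sigma,
        tau=tau,
        von_mises=vm,
        areas=field.areas[mask],
        sigma_scale=e_kpa,
    )


def compression_barrier(
    states: SpringStates, field: SpringField, params: PDLParams
) -> np.ndarray:
    """Energy penalty [N*mm] per active block for over-compression.

    Zero while the normal projection stays above c*l0, then a stiff C^1
    quadratic: 1/2 * (barrier_multiplier * k_n) * (c*l0 - p)^2.
    """
    l0 = field.rest_length
    floor = params.compression_limit_fraction * l0
    deficit = np.maximum(floor - states.normal_projection, 0.0)
    k_b = params.barrier_multiplier * field.k_normal[states.block_indices]
    return 0.5 * k_b * deficit**2


def prune_exceeding(
    field: SpringField, pose: RigidPose, gingival_plane: Plane
) -> int:
    """Permanently deactivate blocks whose tooth point crossed the gum line.

    A block is removed when its tooth-side point, in the world frame, has
    positive signed distance to the gingival plane (occlusal side).
    Returns the number of blocks removed by this call.
    """
    mask = field.active
    if not mask.any():
        return 0
    x = field.world_tooth_points(pose)[mask]
    sd = signed_distance(gingival_plane, x)
    out = np.flatnonzero(mask)[sd > 0]
    field.active[out] = False
    return int(out.size)
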