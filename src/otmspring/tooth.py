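"""Parametric single-rooted canine-like tooth generator.

The patient-specific canine geometry the model was originally exercised on
is not distributable, so experiments run on a watertight parametric
stand-in: a tapered elliptic root (gingival plane z = 0 up to a rounded
apex at z = root_length) joined to a bulged crown ending in an incisal tip.

Canonical frame (upper-right canine): +z apical, -z occlusal, +x distal,
+y palatal. The gingival plane is z = 0 with its normal pointing occlusally
(-z). The long axis is +z in canonical placement; :func:`orient_tooth`
tips the tooth about the mesiodistal (x) axis by the angulation alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np

from .geometry import (
    DEFAULT_GINGIVAL_PLANE,
    Plane,
    RigidPose,
    TriMesh,
    rotation_about_axis,
    signed_distance,
)

__all__ = ["ToothParams", "ToothModel", "generate_canine", "orient_tooth"]


@dataclass(frozen=True)
class ToothParams:
    """Dimensions and mesh resolution of the synthetic canine.

    Defaults are generic canine proportions: 16 mm root, 10 mm crown,
    4.0 x 3.5 mm mesiodistal x buccopalatal root base radii, taper
    exponent 1.5. Resolution is circumferential x axial vertex counts;
    ``jitter`` adds seeded radial surface noise (fraction of local radius).
    """

    root_length: float = 16.0
    crown_height: float = 10.0
    root_radius_md: float = 4.0   # mesiodistal (x) half-width at the base
    root_radius_bp: float = 3.5   # buccopalatal (y) half-width at the base
    taper: float = 1.5
    n_circ: int = 32
    n_axial_root: int = 30
    n_axial_crown: int = 16
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("root_length", "crown_height", "root_radius_md", "root_radius_bp", "taper"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_circ < 16 or self.n_axial_root + self.n_axial_crown < 16:
            raise ValueError("mesh resolution must be at least 16 x 16")
        if self.n_circ % 4:
            raise ValueError("n_circ must be a multiple of 4 (landmarks lie on +/-y)")
        if self.n_axial_crown % 2:
            raise ValueError("n_axial_crown must be even (mid-crown landmark ring)")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass
class ToothModel:
    """Generated tooth: mesh + named anatomical landmarks.

    ``landmarks`` holds ``apex``, ``crown_tip``, ``occlusal_anchor``,
    ``mid_buccal`` and ``mid_palatal`` (plus any appliance attachment
    points registered later); all move rigidly with the tooth.
    """

    mesh: TriMesh
    landmarks: dict[str, np.ndarray]
    long_axis: np.ndarray
    params: ToothParams
    alpha_deg: float = 0.0
    gingival_plane: Plane = field(default_factory=lambda: DEFAULT_GINGIVAL_PLANE)
    #: faces on the anatomical root surface (cementum), fixed at generation;
    #: only these can carry PDL springs, however the tooth is oriented
    anatomical_root_faces: np.ndarray | None = None

    @property
    def root_faces(self) -> np.ndarray:
        """Indices of faces whose centroid lies apical to the gingival plane."""
        sd = signed_distance(self.gingival_plane, self.mesh.face_centroids)
        return np.flatnonzero(sd < 0)

    def landmark(self, name: str) -> np.ndarray:
        try:
            return self.landmarks[name]
        except KeyError:
            raise KeyError(
                f"unknown landmark {name!r}; available: {sorted(self.landmarks)}"
            ) from None

    def add_landmark(self, name: str, point: np.ndarray) -> None:
        self.landmarks[name] = np.asarray(point, dtype=float).reshape(3)

    def save(self, mesh_path: str | Path, landmarks_path: str | Path | None = None) -> None:
        """Write the mesh (format from extension) and a JSON landmark sidecar."""
        from .geometry import save_mesh

        save_mesh(self.mesh, mesh_path)
        if landmarks_path is not None:
            payload = {k: list(map(float, v)) for k, v in self.landmarks.items()}
            Path(landmarks_path).write_text(json.dumps(payload, indent=1))


def _root_profile(u: np.ndarray, taper: float) -> np.ndarray:
    # 1 at the base (u=0), 0 at the apex (u=1), rounded near the tip
    return (1.0 - u**2) ** (taper / 2.0)


def _crown_profile(v: np.ndarray) -> np.ndarray:
    # slight buccolingual bulge, tapering to the incisal tip at v=1
    return (1.0 - v**3) ** 0.5 * (1.0 + 0.15 * np.sin(np.pi * v))


def generate_canine(params: ToothParams | None = None) -> ToothModel:
    """Build the watertight synthetic canine in canonical placement."""
    p = params or ToothParams()
    nc, nar, nac = p.n_circ, p.n_axial_root, p.n_axial_crown
    theta = 2.0 * np.pi * np.arange(nc) / nc
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # area-preserving polygon correction: an inscribed n-gon under-covers
    # the ellipse cross-section by O(1/n^2); scaling the ring radius makes
    # section area (hence enclosed volume) second-order accurate
    poly_scale = np.sqrt((2.0 * np.pi / nc) / np.sin(2.0 * np.pi / nc))

    # ring descriptions bottom-up: crown rings (z<0, incisal side first),
    # shared cervical ring at z=0, then root rings up to (not incl.) the apex
    ring_z: list[float] = []
    ring_s: list[float] = []
    for j in range(nac - 1, 0, -1):  # v = j/nac, v->1 is the incisal tip
        v = j / nac
        ring_z.append(-p.crown_height * v)
        ring_s.append(float(_crown_profile(np.array(v))))
    ring_z.append(0.0)
    ring_s.append(1.0)
    for j in range(1, nar):
        u = j / nar
        ring_z.append(p.root_length * u)
        ring_s.append(float(_root_profile(np.array(u), p.taper)))

    n_rings = len(ring_z)
    rng = np.random.default_rng(p.seed)
    verts = np.empty((n_rings * nc + 2, 3))
    for i, (z, s) in enumerate(zip(ring_z, ring_s)):
        scale = s * poly_scale * np.ones(nc)
        if p.jitter > 0:
            scale = scale * (1.0 + p.jitter * rng.standard_normal(nc))
        verts[i * nc:(i + 1) * nc, 0] = p.root_radius_md * scale * cos_t
        verts[i * nc:(i + 1) * nc, 1] = p.root_radius_bp * scale * sin_t
        verts[i * nc:(i + 1) * nc, 2] = z
    tip_idx = n_rings * nc          # incisal tip, z = -crown_height
    apex_idx = n_rings * nc + 1     # root apex, z = +root_length
    verts[tip_idx] = (0.0, 0.0, -p.crown_height)
    verts[apex_idx] = (0.0, 0.0, p.root_length)

    faces: list[tuple[int, int, int]] = []
    nxt = np.roll(np.arange(nc), -1)
    for r in range(n_rings - 1):
        a = r * nc + np.arange(nc)
        b = (r + 1) * nc + np.arange(nc)
        for i in range(nc):
            faces.append((a[i], a[nxt[i]], b[nxt[i]]))
            faces.append((a[i], b[nxt[i]], b[i]))
    first = np.arange(nc)
    last = (n_rings - 1) * nc + np.arange(nc)
    for i in range(nc):  # fans: tip below the first ring, apex above the last
        faces.append((tip_idx, first[nxt[i]], first[i]))
        faces.append((apex_idx, last[i], last[nxt[i]]))

    mesh = TriMesh(verts, np.array(faces, dtype=np.int64))

    # landmarks: +y is palatal, -y buccal; mid-crown ring sits at v = 1/2
    mid_ring = (nac - 1) - (nac // 2)  # ring index where v = 0.5
    i_pal = nc // 4        # theta = 90 deg  -> +y
    i_buc = 3 * nc // 4    # theta = 270 deg -> -y
    landmarks = {
        "apex": verts[apex_idx].copy(),
        "crown_tip": verts[tip_idx].copy(),
        "occlusal_anchor": verts[tip_idx].copy(),
        "mid_buccal": verts[mid_ring * nc + i_buc].copy(),
        "mid_palatal": verts[mid_ring * nc + i_pal].copy(),
    }
    return ToothModel(
        mesh=mesh,
        landmarks=landmarks,
        long_axis=np.array([0.0, 0.0, 1.0]),
        params=p,
        anatomical_root_faces=np.flatnonzero(mesh.face_centroids[:, 2] > 0.0),
    )


def orient_tooth(model: ToothModel, alpha_deg: float) -> ToothModel:
    """Tip the tooth by the angulation alpha about the mesiodistal axis.

    Rotation is about +x through the intersection of the long axis and the
    gingival plane (the origin in canonical placement); the plane itself is
    unchanged, so |alpha| is the angle between the long axis and the
    perpendicular to the gingival plane. Positive alpha tips the apex
    buccally (toward -y).
    """
    if abs(alpha_deg) >= 90.0:
        raise ValueError("|alpha| must be < 90 degrees")
    rot = rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.deg2rad(alpha_deg))
    pose = RigidPose(rot, np.zeros(3))
    return replace(
        model,
        mesh=model.mesh.transformed(pose),
        landmarks={k: pose.apply(v) for k, v in model.landmarks.items()},
        long_axis=rot @ model.long_axis,
        alpha_deg=model.alpha_deg + alpha_deg,
    )
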