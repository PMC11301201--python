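"""Orthodontic load models: constant forces, force couples, coil springs.

Every appliance contributes a potential energy U(pose) and, through its
gradient with respect to the attachment point's world position, a
generalized force on the tooth:

* ConstantForce  U = -F . x_att           (dead load, fixed direction)
* CoilSpring     U = 1/2 k (|x_att - anchor| - l_r)^2   (Hookean coil)

A force couple is simply two equal and opposite ConstantForce items in an
:class:`ApplianceSet`; it contributes a pure moment. Coil initial force
follows Hooke's law F_i = k (l_l - l_r) with activation length l_l and
rest length l_r; gram-force converts with g = 9.8 m/s^2 exactly, so
300 gf = 2.94 N.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import RigidPose

__all__ = [
    "ConstantForce",
    "CoilSpring",
    "ApplianceSet",
    "gram_force_to_newton",
    "initial_force",
    "appliance_energy",
    "appliance_force",
    "load_coil_catalog",
    "default_coil_catalog",
]

#: N per gram-force at g = 9.8 m/s^2 (reproduces the printed 300 gf = 2.94 N)
GF_TO_N = 0.0098


def gram_force_to_newton(gf: float) -> float:
    """Convert gram-force to newtons (g = 9.8 m/s^2 exactly)."""
    if gf < 0:
        raise ValueError("gram-force must be >= 0")
    return gf * GF_TO_N


@dataclass(frozen=True)
class ConstantForce:
    """Dead load of fixed world-frame direction applied at a landmark."""

    magnitude: float            # N
    direction: tuple[float, float, float]
    attachment: str             # landmark name (tooth body frame)

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("force magnitude must be >= 0")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            if n < 1e-12:
                raise ValueError("force direction must be non-zero")
            object.__setattr__(self, "direction", tuple(d / n))

    @property
    def force_vector(self) -> np.ndarray:
        return self.magnitude * np.asarray(self.direction)


@dataclass(frozen=True)
class CoilSpring:
    """Hookean coil from a tooth landmark to a fixed world anchor.

    ``activation_length`` is the stretched length at placement; coils act
    in traction only in the sense that activation >= rest is required at
    setup (the energy itself is symmetric quadratic).
    """

    stiffness: float            # N/mm
    rest_length: float          # mm
    activation_length: float    # mm
    attachment: str
    anchor: tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("coil stiffness must be > 0")
        if self.rest_length <= 0:
            raise ValueError("coil rest length must be > 0")
        if self.activation_length < self.rest_length:
            raise ValueError("activation length must be >= rest length (coils act in traction)")


def initial_force(coil: CoilSpring) -> float:
    """Hooke's-law placement force F_i = k (l_l - l_r) [N]."""
    return coil.stiffness * (coil.activation_length - coil.rest_length)


@dataclass(frozen=True)
class CoilTemplate:
    """Catalog row: a coil before it is anchored in a scenario."""

    label: str
    rest_length: float
    stiffness: float
    activation_length: float

    @property
    def initial_force(self) -> float:
        return self.stiffness * (self.activation_length - self.rest_length)

    def place(self, attachment: str, attachment_point: np.ndarray,
              direction: np.ndarray) -> CoilSpring:
        """Anchor the coil so its placement force acts along ``direction``.

        The world anchor is set one activation length from the attachment
        point along the unit force direction, then stays fixed as the
        tooth moves.
        """
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        anchor = np.asarray(attachment_point, dtype=float) + self.activation_length * d
        return CoilSpring(
            stiffness=self.stiffness,
            rest_length=self.rest_length,
            activation_length=self.activation_length,
            attachment=attachment,
            anchor=tuple(anchor),
            label=self.label,
        )


class ApplianceSet:
    """Ordered collection of appliances acting on one tooth."""

    def __init__(self, items: list[ConstantForce | CoilSpring] | None = None):
        self.items: list[ConstantForce | CoilSpring] = list(items or [])

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def validate(self, landmarks: dict[str, np.ndarray]) -> None:
        for item in self.items:
            if item.attachment not in landmarks:
                raise KeyError(f"appliance attachment {item.attachment!r} is not a landmark")


def _world_attachment(item, pose: RigidPose, landmarks: dict[str, np.ndarray]) -> np.ndarray:
    return pose.apply(landmarks[item.attachment])


def appliance_energy(
    item: ConstantForce | CoilSpring, pose: RigidPose, landmarks: dict[str, np.ndarray]
) -> float:
    """Potential energy [N*mm] of one appliance at the given pose."""
    x = _world_attachment(item, pose, landmarks)
    if isinstance(item, ConstantForce):
        return float(-item.force_vector @ x)
    d = x - np.asarray(item.anchor)
    length = float(np.linalg.norm(d))
    if length < 1e-12:
        raise ValueError("coil attachment coincides with its anchor; direction undefined")
    return 0.5 * item.stiffness * (length - item.rest_length) ** 2


def appliance_force(
    item: ConstantForce | CoilSpring, pose: RigidPose, landmarks: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """(force on the tooth [N], world attachment point) for one appliance."""
    x = _world_attachment(item, pose, landmarks)
    if isinstance(item, ConstantForce):
        return item.force_vector.copy(), x
    d = x - np.asarray(item.anchor)
    length = float(np.linalg.norm(d))
    if length < 1e-12:
        raise ValueError("coil attachment coincides with its anchor; direction undefined")
    # force pulls the attachment toward the anchor when stretched
    return -item.stiffness * (length - item.rest_length) * d / length, x


_CATALOG_COLUMNS = ["model_label", "rest_length_mm", "stiffness_N_per_mm", "activation_length_mm"]


def load_coil_catalog(path: str | Path) -> list[CoilTemplate]:
    """Read a coil catalog CSV into validated templates."""
    df = pd.read_csv(path)
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coil catalog missing column(s): {missing}")
    if len(df) == 0:
        raise ValueError("coil catalog is empty")
    out = []
    for _, row in df.iterrows():
        if row["stiffness_N_per_mm"] <= 0:
            raise ValueError(f"non-positive stiffness for coil {row['model_label']!r}")
        if row["rest_length_mm"] <= 0:
            raise ValueError(f"non-positive rest length for coil {row['model_label']!r}")
        if row["activation_length_mm"] < row["rest_length_mm"]:
            raise ValueError(f"activation < rest length for coil {row['model_label']!r}")
        out.append(CoilTemplate(
            label=str(row["model_label"]),
            rest_length=float(row["rest_length_mm"]),
            stiffness=float(row["stiffness_N_per_mm"]),
            activation_length=float(row["activation_length_mm"]),
        ))
    return out


def default_coil_catalog() -> list[CoilTemplate]:
    """Packaged synthetic stand-in catalog (16 coils, 1.96-7.84 N).

    Labels encode rest length [mm] and stiffness class (L/M/H; '+' marks a
    longer activation of the same coil). The real commercial constants are
    not public, so this catalog is a documented synthetic surrogate whose
    Hooke's-law initial forces span 200-800 gf.
    """
    ref = resources.files("otmspring").joinpath("data/coil_catalog_synthetic.csv")
    with resources.as_file(ref) as p:
        return load_coil_catalog(p)
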