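"""Instantaneous rigid-body equilibrium by energy minimization.

Stage-1 mechanics: the tooth moves instantly, as a rigid body, to the
pose that minimizes the total energy

    U(pose) = sum over active blocks [ 1/2 k_n (l - l0)^2
                                       + 1/2 k_s (l0 tan theta)^2
                                       + barrier ]
              + sum over appliances U_appliance

The pose has six coordinates: a world translation u [mm] and a rotation
increment about the field's rotation center, expressed as L * phi [mm]
with phi in radians and L a characteristic length, so all six coordinates
share units and the descent is well conditioned. Minimization is
backtracking (Armijo) gradient descent with an adaptively grown step;
accepted steps can prune spring blocks that crossed the gingival line, so
the energy sequence over accepted steps is non-increasing. The gradient
is analytic (and checked against central finite differences in the test
suite).

The solver is deterministic: identical inputs give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial.transform import Rotation

from .appliance import ApplianceSet, CoilSpring, ConstantForce
from .geometry import Plane, RigidPose
from .pdl import TAN_EPS, PDLParams, SpringField, compute_state, prune_exceeding

__all__ = ["SolverSettings", "EquilibriumResult", "total_energy", "solve_instantaneous", "net_reaction"]


@dataclass(frozen=True)
class SolverSettings:
    """Gradient-flow settings.

    ``gtol`` is on the scaled 6-gradient norm [N]; ``etol`` on the energy
    decrease [N*mm]. ``dof_mask`` restricts the descent to a subset of
    (ux, uy, uz, phi_x, phi_y, phi_z), which the oracle tests use.
    ``char_length`` converts rotation radians to mm-equivalent
    coordinates; None means "use the field's spatial extent".
    """

    max_iterations: int = 50_000
    gtol: float = 1e-6
    etol: float = 1e-12
    initial_step: float | None = None
    backtrack: float = 0.5
    grow: float = 1.6
    armijo: float = 1e-4
    prune_during_descent: bool = True
    char_length: float | None = None
    dof_mask: tuple[bool, bool, bool, bool, bool, bool] | None = None

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.gtol <= 0 or self.etol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class EquilibriumResult:
    """Outcome of one instantaneous solve."""

    pose: RigidPose
    energy_trajectory: np.ndarray
    iterations: int
    converged: bool
    residual_norm: float          # scaled 6-gradient norm [N]
    residual_force: np.ndarray    # translational gradient [N]
    residual_moment: np.ndarray   # rotational gradient [N*mm]
    pruned_blocks: int
    states: object = None         # SpringStates at the final pose

    def to_json_dict(self) -> dict:
        return {
            "translation_mm": self.pose.translation.tolist(),
            "rotation": self.pose.rotation.tolist(),
            "final_energy_Nmm": float(self.energy_trajectory[-1]),
            "iterations": self.iterations,
            "converged": self.converged,
            "residual_norm_N": self.residual_norm,
            "pruned_blocks": self.pruned_blocks,
        }


def _spring_energy_grad(field: SpringField, pose: RigidPose, params: PDLParams,
                        center: np.ndarray, want_grad: bool = True):
    """Energy of the spring field and its gradient at the pose.

    Returns (E, g_t [N], g_w [N*mm]); g_w is the gradient with respect to
    a rotation increment about ``center``.
    """
    mask = field.active
    if not mask.any():
        z = np.zeros(3)
        return 0.0, z, z
    x = field.tooth_points[mask] @ pose.rotation.T + pose.translation
    d = field.bone_anchors[mask] - x
    n = field.rest_axes[mask]
    l0 = field.rest_length
    kn = field.k_normal[mask]
    ks = field.k_shear[mask]

    length = np.linalg.norm(d, axis=1)
    proj = np.einsum("ij,ij->i", d, n)
    tvec = d - proj[:, None] * n
    s = np.linalg.norm(tvec, axis=1)
    p_eff = np.maximum(proj, TAN_EPS)
    q = l0 * s / p_eff  # shear deformation measure l0 tan(theta) [mm]

    stretch = length - l0
    floor = params.compression_limit_fraction * l0
    deficit = np.maximum(floor - proj, 0.0)
    kb = params.barrier_multiplier * kn

    energy = float(
        0.5 * (kn * stretch**2).sum()
        + 0.5 * (ks * q**2).sum()
        + 0.5 * (kb * deficit**2).sum()
    )
    if not want_grad:
        return energy, None, None

    # dU/dx per block (x = world tooth point); d = anchor - x so dl/dx = -d_hat
    safe_l = np.maximum(length, 1e-30)
    g = -(kn * stretch / safe_l)[:, None] * d
    # shear: ds/dx = -t_hat, dproj/dx = -n (proj derivative only where unclamped)
    safe_s = np.maximum(s, 1e-30)
    coeff = ks * q * l0
    g += -(coeff / (p_eff * safe_s))[:, None] * tvec
    unclamped = proj > TAN_EPS
    g += ((coeff * s / p_eff**2) * unclamped)[:, None] * n
    # barrier: dU/dx = kb * deficit * n
    g += (kb * deficit)[:, None] * n

    g_t = g.sum(axis=0)
    g_w = np.cross(x - center, g).sum(axis=0)
    return energy, g_t, g_w


def _appliance_energy_grad(appliances: ApplianceSet, pose: RigidPose,
                           landmarks: dict, center: np.ndarray,
                           want_grad: bool = True):
    energy = 0.0
    g_t = np.zeros(3)
    g_w = np.zeros(3)
    for item in appliances:
        x = pose.apply(landmarks[item.attachment])
        if isinstance(item, ConstantForce):
            f = item.force_vector
            energy += float(-f @ x)
            if want_grad:
                g_t += -f
                g_w += np.cross(x - center, -f)
        elif isinstance(item, CoilSpring):
            dvec = x - np.asarray(item.anchor)
            length = float(np.linalg.norm(dvec))
            if length < 1e-12:
                raise ValueError("coil attachment coincides with its anchor; direction undefined")
            energy += 0.5 * item.stiffness * (length - item.rest_length) ** 2
            if want_grad:
                gx = item.stiffness * (length - item.rest_length) * dvec / length
                g_t += gx
                g_w += np.cross(x - center, gx)
        else:
            raise TypeError(f"unknown appliance type {type(item)!r}")
    return energy, g_t, g_w


def total_energy(
    field: SpringField,
    appliances: ApplianceSet | None,
    pose: RigidPose,
    params: PDLParams,
    landmarks: dict | None = None,
) -> float:
    """Total energy [N*mm] of PDL springs (+ barrier) and appliances."""
    center = field.rotation_center
    e, _, _ = _spring_energy_grad(field, pose, params, center, want_grad=False)
    if appliances is not None and len(appliances):
        if landmarks is None:
            raise ValueError("landmarks required to evaluate appliance energy")
        ea, _, _ = _appliance_energy_grad(appliances, pose, landmarks, center, want_grad=False)
        e += ea
    return e


def energy_and_gradient(
    field: SpringField,
    appliances: ApplianceSet | None,
    pose: RigidPose,
    params: PDLParams,
    landmarks: dict | None = None,
    char_length: float = 1.0,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """(energy, scaled 6-gradient, translational grad [N], rotational grad [N*mm]).

    The scaled gradient stacks (g_t, g_w / L) so every coordinate is in N.
    """
    center = field.rotation_center
    e, g_t, g_w = _spring_energy_grad(field, pose, params, center)
    if appliances is not None and len(appliances):
        if landmarks is None:
            raise ValueError("landmarks required to evaluate appliance energy")
        ea, ga_t, ga_w = _appliance_energy_grad(appliances, pose, landmarks, center)
        e += ea
        g_t = g_t + ga_t
        g_w = g_w + ga_w
    g6 = np.concatenate([g_t, g_w / char_length])
    return e, g6, g_t, g_w


def _step_pose(pose: RigidPose, delta: np.ndarray, center: np.ndarray,
               char_length: float) -> RigidPose:
    """Apply a 6-coordinate increment: translation + rotation about center."""
    u = delta[:3]
    phi = delta[3:] / char_length
    rot = Rotation.from_rotvec(phi).as_matrix()
    new_r = rot @ pose.rotation
    new_t = rot @ (pose.translation - center) + center + u
    return RigidPose(new_r, new_t)


def _auto_char_length(field: SpringField) -> float:
    ext = field.tooth_points.max(axis=0) - field.tooth_points.min(axis=0)
    return max(float(np.linalg.norm(ext)) / 2.0, 1.0)


def solve_instantaneous(
    field: SpringField,
    appliances: ApplianceSet | None,
    start_pose: RigidPose,
    settings: SolverSettings,
    params: PDLParams,
    landmarks: dict | None = None,
    gingival_plane: Plane | None = None,
) -> EquilibriumResult:
    """Backtracking gradient descent over the six pose coordinates.

    When ``prune_during_descent`` and a gingival plane is given, blocks
    that cross the plane are removed after each accepted step (removing a
    block removes its non-negative energy, preserving monotonicity).
    A run that hits ``max_iterations`` is returned flagged non-converged,
    not raised.
    """
    L = settings.char_length or _auto_char_length(field)
    center = field.rotation_center
    mask6 = np.ones(6) if settings.dof_mask is None else np.asarray(settings.dof_mask, dtype=float)

    pose = start_pose
    pruned_total = 0
    if settings.prune_during_descent and gingival_plane is not None:
        pruned_total += prune_exceeding(field, pose, gingival_plane)

    e, g6, g_t, g_w = energy_and_gradient(field, appliances, pose, params, landmarks, L)
    g6 = g6 * mask6
    energies = [e]

    # initial step ~ inverse of the aggregate spring stiffness
    k_total = float(field.k_normal[field.active].sum()) or 1.0
    step = settings.initial_step or 1.0 / k_total
    converged = False
    it = 0
    for it in range(1, settings.max_iterations + 1):
        gnorm = float(np.linalg.norm(g6))
        if gnorm < settings.gtol:
            converged = True
            break
        # Armijo backtracking along -g6
        accepted = False
        while step > 1e-18:
            trial = _step_pose(pose, -step * g6, center, L)
            e_trial = total_energy(field, appliances, trial, params, landmarks)
            if e_trial <= e - settings.armijo * step * gnorm**2:
                accepted = True
                break
            step *= settings.backtrack
        if not accepted:
            # no float-representable step decreases the energy: stationary
            converged = True
            break
        decrease = e - e_trial
        pose = trial
        if settings.prune_during_descent and gingival_plane is not None:
            removed = prune_exceeding(field, pose, gingival_plane)
            if removed:
                pruned_total += removed
                e_trial = total_energy(field, appliances, pose, params, landmarks)
        e = e_trial
        energies.append(e)
        g6 = energy_and_gradient(field, appliances, pose, params, landmarks, L)[1] * mask6
        step *= settings.grow
        if decrease < settings.etol:
            converged = True
            break

    _, g6f, g_t, g_w = energy_and_gradient(field, appliances, pose, params, landmarks, L)
    g6f = g6f * mask6
    return EquilibriumResult(
        pose=pose,
        energy_trajectory=np.asarray(energies),
        iterations=it,
        converged=converged,
        residual_norm=float(np.linalg.norm(g6f)),
        residual_force=g_t * mask6[:3],
        residual_moment=g_w * mask6[3:],
        pruned_blocks=pruned_total,
        states=compute_state(field, pose, params),
    )


def net_reaction(
    field: SpringField,
    pose: RigidPose,
    params: PDLParams,
    about: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Net PDL reaction on the tooth: (force [N], moment [N*mm]).

    The moment is taken about ``about`` (default: the field's rotation
    center). At a converged equilibrium under an applied load, the
    reaction balances the load: F_reaction = -F_applied.
    """
    ref = field.rotation_center if about is None else np.asarray(about, dtype=float)
    _, g_t, g_w = _spring_energy_grad(field, pose, params, ref)
    # force on the tooth is minus the energy gradient
    return -g_t, -g_w
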