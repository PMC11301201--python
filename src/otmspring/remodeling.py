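"""Stress-dependent bone remodeling and the full tooth-movement loop.

Stage-3 biology: a spring block under sufficient strain drives relocation
of its bone anchor toward the position that restores the rest geometry at
the current tooth pose (anchor target = tooth point + l0 * current
outward normal). The anchor moves at a rate proportional to the block's
Von Mises stress, with resorption (compressed side, sigma < 0) faster
than formation (tension side), capped per step, and gated by the minimum
bone-remodeling strain of 1500 microstrain. One remodeling step is one
abstract iteration — the model carries no physical time scale.

The full orthodontic-tooth-movement loop alternates instantaneous
energy-minimizing solves with remodeling steps, pruning spring blocks
that cross the gingival line, until the appliance unloads, progress
stalls, a target travel is reached, or a cycle cap hits. "Anchorage
movement" is the displacement of the (first) appliance attachment point
from its initial world position; checkpoint summaries are taken at the
first recorded sample at or beyond each requested distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .appliance import ApplianceSet, appliance_force
from .geometry import Plane, RigidPose
from .pdl import PDLParams, SpringField, compute_state, prune_exceeding
from .solver import EquilibriumResult, SolverSettings, solve_instantaneous
from .stress import StressSummary, summarize

__all__ = [
    "RemodelingParams",
    "OTMSample",
    "OTMResult",
    "remodeling_step",
    "run_otm",
    "checkpoint_summaries",
]

#: minimum strain for bone remodeling to proceed (1500 microstrain)
REMODELING_STRAIN_THRESHOLD = 1500e-6


@dataclass(frozen=True)
class RemodelingParams:
    """Rate law and stopping criteria for the remodeling loop.

    Anchor speed is eta * sigma_vm [mm per kPa-step], eta depending on the
    side: ``eta_resorption`` (compression) > ``eta_formation`` (tension),
    default ratio 2:1, both capped at ``max_step`` mm per step. The loop
    stops when every appliance force falls below ``f_stop``, the per-cycle
    anchorage-movement increment falls below ``d_stop``, ``target_movement``
    is reached, or ``max_cycles`` elapse.
    """

    eta_resorption: float = 5e-4   # mm per (kPa * step)
    eta_formation: float = 2.5e-4  # mm per (kPa * step)
    strain_threshold: float = REMODELING_STRAIN_THRESHOLD
    max_step: float = 0.02         # mm per step per anchor
    f_stop: float = 0.02           # N
    d_stop: float = 1e-5           # mm per cycle
    max_cycles: int = 500
    target_movement: float | None = None  # mm

    def __post_init__(self) -> None:
        if not (self.eta_resorption > self.eta_formation > 0):
            raise ValueError("require eta_resorption > eta_formation > 0")
        if self.strain_threshold < 0:
            raise ValueError("strain_threshold must be >= 0")
        if self.max_step <= 0:
            raise ValueError("max_step must be > 0")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


def remodeling_step(
    field: SpringField,
    pose: RigidPose,
    params: PDLParams,
    rparams: RemodelingParams,
) -> float:
    """Relax bone anchors of sufficiently strained blocks; return the
    largest anchor displacement [mm].

    For each active block with |l - l0| / l0 >= the strain threshold the
    anchor moves toward ``tooth point + l0 * current outward normal`` by
    min(eta * sigma_vm, max_step), clamped at the target; the block's
    rest axis is re-derived from the new anchor so a fully relaxed block
    is again an undeformed normal spring.
    """
    states = compute_state(field, pose, params)
    if states.block_indices.size == 0:
        return 0.0
    strain = np.abs(states.length - field.rest_length) / field.rest_length
    sel = strain >= rparams.strain_threshold
    if not sel.any():
        return 0.0
    idx = states.block_indices[sel]
    x = field.world_tooth_points(pose)[idx]
    cur_normals = field.world_normals(pose)[idx]
    target = x + field.rest_length * cur_normals

    eta = np.where(states.sigma[sel] < 0.0, rparams.eta_resorption, rparams.eta_formation)
    speed = np.minimum(eta * states.von_mises[sel], rparams.max_step)

    to_target = target - field.bone_anchors[idx]
    dist = np.linalg.norm(to_target, axis=1)
    move = np.minimum(speed, dist)
    nonzero = dist > 1e-15
    shift = np.zeros_like(to_target)
    shift[nonzero] = (move[nonzero] / dist[nonzero])[:, None] * to_target[nonzero]
    field.bone_anchors[idx] += shift

    # re-derive the rest axis from the new anchor geometry
    d = field.bone_anchors[idx] - x
    dn = np.linalg.norm(d, axis=1)
    ok = dn > 1e-12
    field.rest_axes[idx[ok]] = d[ok] / dn[ok][:, None]
    return float(move.max()) if move.size else 0.0


@dataclass
class OTMSample:
    """One recorded cycle of the movement loop."""

    cycle: int
    movement: float               # cumulative anchorage movement [mm]
    pose: RigidPose
    summary: StressSummary
    active_blocks: int
    max_appliance_force: float    # N


@dataclass
class OTMResult:
    """Trajectory of the instantaneous-solve / remodeling alternation."""

    samples: list[OTMSample]
    status: str                   # why the loop stopped
    pruned_blocks: int

    @property
    def movements(self) -> np.ndarray:
        return np.array([s.movement for s in self.samples])

    @property
    def final(self) -> OTMSample:
        return self.samples[-1]

    def trajectory_frame(self):
        """Trajectory as a pandas DataFrame (cycle, movement, stresses...)."""
        import pandas as pd

        return pd.DataFrame([
            {
                "cycle": s.cycle,
                "movement_mm": s.movement,
                "mean_kPa": s.summary.mean,
                "max_kPa": s.summary.max,
                "std_kPa": s.summary.std,
                "active_blocks": s.active_blocks,
                "appliance_force_N": s.max_appliance_force,
            }
            for s in self.samples
        ])


def _max_appliance_force(appliances: ApplianceSet, pose: RigidPose, landmarks: dict) -> float:
    forces = [np.linalg.norm(appliance_force(a, pose, landmarks)[0]) for a in appliances]
    return float(max(forces)) if forces else 0.0


def run_otm(
    field: SpringField,
    appliances: ApplianceSet,
    landmarks: dict,
    params: PDLParams,
    solver_settings: SolverSettings,
    rparams: RemodelingParams,
    gingival_plane: Plane,
) -> OTMResult:
    """Alternate instantaneous solves and remodeling steps to equilibrium.

    Raises RuntimeError if an instantaneous solve fails to converge (the
    loop cannot meaningfully continue from a non-equilibrium).
    """
    if len(appliances) == 0:
        states = compute_state(field, RigidPose.identity(), params)
        sample = OTMSample(0, 0.0, RigidPose.identity(), summarize(states), field.n_active, 0.0)
        return OTMResult([sample], "no appliance: nothing to do", 0)

    attachment = appliances.items[0].attachment
    x0 = np.asarray(landmarks[attachment], dtype=float)

    pose = RigidPose.identity()
    samples: list[OTMSample] = []
    pruned_total = 0
    status = "max_cycles reached"

    for cycle in range(rparams.max_cycles + 1):
        res: EquilibriumResult = solve_instantaneous(
            field, appliances, pose, solver_settings, params, landmarks, gingival_plane
        )
        if not res.converged:
            raise RuntimeError(
                f"instantaneous solve did not converge at cycle {cycle} "
                f"(residual {res.residual_norm:.3g} N after {res.iterations} iterations)"
            )
        pose = res.pose
        pruned_total += res.pruned_blocks
        if field.n_active == 0:
            status = "all spring blocks removed"
            break
        movement = float(np.linalg.norm(pose.apply(landmarks[attachment]) - x0))
        fmax = _max_appliance_force(appliances, pose, landmarks)
        samples.append(OTMSample(cycle, movement, pose, summarize(res.states),
                                 field.n_active, fmax))

        if fmax < rparams.f_stop:
            status = "appliance unloaded"
            break
        if rparams.target_movement is not None and movement >= rparams.target_movement:
            status = "target movement reached"
            break
        if len(samples) >= 2 and abs(samples[-1].movement - samples[-2].movement) < rparams.d_stop:
            status = "movement stalled"
            break
        if cycle == rparams.max_cycles:
            break

        moved = remodeling_step(field, pose, params, rparams)
        if moved == 0.0 and len(samples) >= 1:
            status = "below remodeling threshold"
            break

    if not samples:  # all blocks pruned on the very first solve
        states = compute_state(field, pose, params)
        raise RuntimeError("no active spring blocks after the first instantaneous solve")
    return OTMResult(samples, status, pruned_total)


def checkpoint_summaries(
    result: OTMResult,
    distances: tuple[float, ...] = (0.25, 1.5, 3.0),
) -> dict[float, StressSummary | None]:
    """Stress summary at the first sample at or beyond each distance [mm].

    Distances the run never reached map to None.
    """
    movements = result.movements
    out: dict[float, StressSummary | None] = {}
    for dist in distances:
        reached = np.flatnonzero(movements >= dist)
        out[dist] = result.samples[reached[0]].summary if reached.size else None
    return out
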