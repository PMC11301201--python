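"""Von Mises stress and field summaries.

The scalar reported throughout is the equivalent Von Mises stress
sigma_vm = sqrt(sigma^2 + 3 tau^2) built from each block's normal stress
sigma and shear stress tau. Field summaries (mean, max, standard
deviation, all in kPa) are area-weighted by default — stiffnesses are
area-normalized, so the area-weighted mean is the physically consistent
surface statistic — with a per-block (unweighted) option.

Field export writes legacy ASCII VTK PolyData with per-face CELL_DATA
arrays (sigma, tau, von_mises, in kPa); faces carrying no active spring
block are marked NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import TriMesh

__all__ = ["StressSummary", "von_mises", "summarize", "export_stress_field", "read_stress_field"]


def von_mises(sigma, tau):
    """Equivalent stress sqrt(sigma^2 + 3 tau^2); elementwise on arrays."""
    sigma = np.asarray(sigma, dtype=float)
    tau = np.asarray(tau, dtype=float)
    out = np.sqrt(sigma**2 + 3.0 * tau**2)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StressSummary:
    """Area-weighted summary of a Von Mises field [kPa]."""

    mean: float
    max: float
    std: float
    n_blocks: int
    total_area: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_kPa": self.mean,
            "max_kPa": self.max,
            "std_kPa": self.std,
            "n_blocks": self.n_blocks,
            "total_area_mm2": self.total_area,
        }


def summarize(
    states,
    areas: np.ndarray | None = None,
    area_weighted: bool = True,
) -> StressSummary:
    """Summarize a Von Mises field over active blocks.

    Accepts either a :class:`~otmspring.pdl.SpringStates` (areas taken
    from it) or a raw sigma_vm array plus ``areas``.
    """
    if hasattr(states, "von_mises"):
        vm = states.von_mises
        areas = states.areas
    else:
        vm = np.asarray(states, dtype=float)
        if areas is None:
            areas = np.ones_like(vm)
        areas = np.asarray(areas, dtype=float)
    if vm.size == 0:
        raise ValueError("cannot summarize an empty stress field")
    w = areas if area_weighted else np.ones_like(vm)
    wsum = w.sum()
    mean = float((w * vm).sum() / wsum)
    var = float((w * (vm - mean) ** 2).sum() / wsum)
    return StressSummary(
        mean=mean,
        max=float(vm.max()),
        std=float(np.sqrt(max(var, 0.0))),
        n_blocks=int(vm.size),
        total_area=float(areas.sum()),
    )


def _face_arrays(mesh: TriMesh, states, field=None) -> dict[str, np.ndarray]:
    n = mesh.n_faces
    out = {k: np.full(n, np.nan) for k in ("sigma", "tau", "von_mises")}
    if field is not None:
        faces = field.face_indices[states.block_indices]
    else:
        faces = states.block_indices
    out["sigma"][faces] = states.sigma
    out["tau"][faces] = states.tau
    out["von_mises"][faces] = states.von_mises
    return out


def export_stress_field(
    mesh: TriMesh,
    states,
    path: str | Path,
    field=None,
) -> Path:
    """Write a stress-colored mesh as legacy ASCII VTK PolyData.

    ``field`` (the SpringField the states came from) maps block indices to
    mesh faces; without it the block indices are taken to be face indices
    directly (the case for a field built over the whole mesh).
    """
    path = Path(path)
    arrays = _face_arrays(mesh, states, field)
    lines = [
        "# vtk DataFile Version 3.0",
        "otmspring PDL stress field [kPa]",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(mesh.vertices)} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in mesh.vertices]
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    lines += ["3 " + " ".join(str(i) for i in f) for f in mesh.faces]
    lines.append(f"CELL_DATA {mesh.n_faces}")
    for name, arr in arrays.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in arr]
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write stress field to {path}: {exc}") from exc
    return path


def read_stress_field(path: str | Path) -> tuple[TriMesh, dict[str, np.ndarray]]:
    """Read back a file written by :func:`export_stress_field`."""
    tokens = Path(path).read_text().splitlines()
    i = 0
    while not tokens[i].startswith("POINTS"):
        i += 1
    n_pts = int(tokens[i].split()[1])
    verts = np.array([[float(x) for x in tokens[i + 1 + j].split()] for j in range(n_pts)])
    i += 1 + n_pts
    assert tokens[i].startswith("POLYGONS")
    n_faces = int(tokens[i].split()[1])
    faces = np.array([[int(x) for x in tokens[i + 1 + j].split()[1:]] for j in range(n_faces)])
    i += 1 + n_faces
    assert tokens[i].startswith("CELL_DATA")
    i += 1
    arrays: dict[str, np.ndarray] = {}
    while i < len(tokens) and tokens[i].startswith("SCALARS"):
        name = tokens[i].split()[1]
        i += 2  # skip LOOKUP_TABLE line
        arrays[name] = np.array([float(tokens[i + j]) for j in range(n_faces)])
        i += n_faces
    return TriMesh(verts, faces), arrays
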