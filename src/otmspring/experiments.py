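"""Scenario construction, batch execution and reporting.

Two packaged experiment families on the synthetic canine:

* Experiment 1 — single 300 gf mesial force at the mid-buccal point
  versus a 2.94 N x 5.72 mm mesial-distal force couple, both run through
  the full movement loop with 0.25 / 1.5 / 3.0 mm checkpoints.
* Experiment 2 — full factorial of tooth angulation alpha in
  {15, 0, -15, -30} degrees x force direction (HF: horizontal distal;
  DF: distal-occlusal at 45 degrees) x a 16-coil catalog = 128
  instantaneous-only scenarios (stresses recorded at the end of the
  instantaneous movement).

Directions are world-frame, fixed by the gingival plane: in the
canonical upper-right-canine frame distal is +x, occlusal is -z, so
HF = (1, 0, 0) and DF = (1, 0, -1)/sqrt(2).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .appliance import (
    ApplianceSet,
    CoilTemplate,
    ConstantForce,
    default_coil_catalog,
    gram_force_to_newton,
    initial_force,
)
from .geometry import DEFAULT_GINGIVAL_PLANE, Plane, RigidPose
from .pdl import PDLParams, build_field
from .remodeling import RemodelingParams, checkpoint_summaries, run_otm
from .solver import SolverSettings, solve_instantaneous
from .stress import StressSummary, summarize
from .tooth import ToothModel, ToothParams, generate_canine, orient_tooth

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "HF_DIRECTION",
    "DF_DIRECTION",
    "build_experiment1_scenarios",
    "build_experiment2_scenarios",
    "run_scenario",
    "run_experiments",
    "write_report",
    "scenario_from_yaml",
]

HF_DIRECTION = (1.0, 0.0, 0.0)
DF_DIRECTION = (1.0 / np.sqrt(2.0), 0.0, -1.0 / np.sqrt(2.0))

#: mesial force direction for the upper-right canine (toward the midline)
MESIAL = (-1.0, 0.0, 0.0)
DISTAL = (1.0, 0.0, 0.0)



@dataclass
class ScenarioConfig:
    """One runnable scenario.

    Exactly one tooth source: ``tooth_params`` (synthetic canine) or a
    pre-built ``tooth``. ``appliance_specs`` are declarative dicts
    resolved against the tooth at run time:

    * {type: constant_force, gf|newtons, direction, attachment[, point]}
    * {type: coil, label?, stiffness, rest_length, activation_length,
       direction, attachment[, point]}

    ``remodeling`` None means instantaneous-only.
    """

    label: str
    alpha_deg: float = 0.0
    tooth_params: ToothParams | None = None
    tooth: ToothModel | None = None
    appliance_specs: list[dict[str, Any]] = dc_field(default_factory=list)
    solver: SolverSettings = dc_field(default_factory=SolverSettings)
    remodeling: RemodelingParams | None = None
    pdl: PDLParams = dc_field(default_factory=PDLParams)
    direction_label: str = ""
    coil_label: str = ""
    checkpoints: tuple[float, ...] = ()
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if not (-89.0 <= self.alpha_deg <= 89.0):
            raise ValueError("alpha must be in [-89, 89] degrees")
        if (self.tooth_params is None) == (self.tooth is None):
            raise ValueError("exactly one of tooth_params / tooth must be given")

    def build_tooth(self) -> ToothModel:
        model = self.tooth if self.tooth is not None else generate_canine(self.tooth_params)
        if self.alpha_deg:
            model = orient_tooth(model, self.alpha_deg)
        return model


def _resolve_appliances(config: ScenarioConfig, tooth: ToothModel) -> ApplianceSet:
    items = []
    for spec in config.appliance_specs:
        kind = spec["type"]
        attachment = spec["attachment"]
        if "point" in spec:  # register an explicit body-frame attachment point
            tooth.add_landmark(attachment, np.asarray(spec["point"], dtype=float))
        if attachment not in tooth.landmarks:
            raise KeyError(f"scenario {config.label!r}: unknown attachment {attachment!r}")
        direction = np.asarray(spec["direction"], dtype=float)
        if kind == "constant_force":
            mag = gram_force_to_newton(spec["gf"]) if "gf" in spec else float(spec["newtons"])
            items.append(ConstantForce(mag, tuple(direction), attachment))
        elif kind == "coil":
            template = CoilTemplate(
                label=spec.get("label", ""),
                rest_length=float(spec["rest_length"]),
                stiffness=float(spec["stiffness"]),
                activation_length=float(spec["activation_length"]),
            )
            items.append(template.place(attachment, tooth.landmark(attachment), direction))
        else:
            raise ValueError(f"unknown appliance type {kind!r}")
    return ApplianceSet(items)


@dataclass
class ScenarioResult:
    """Outcome of one scenario (or its recorded failure)."""

    label: str
    alpha_deg: float
    direction: str
    coil: str
    initial_force_N: float
    summary: StressSummary | None = None
    checkpoints: dict[float, StressSummary | None] | None = None
    overall_max_kPa: float | None = None
    otm: object = None
    equilibrium: object = None
    error: str | None = None

    def row(self) -> dict[str, Any]:
        r = {
            "label": self.label,
            "alpha_deg": self.alpha_deg,
            "direction": self.direction,
            "coil": self.coil,
            "initial_force_N": round(self.initial_force_N, 6),
        }
        if self.error is not None:
            r.update(mean_kPa=np.nan, std_kPa=np.nan, max_kPa=np.nan, error=self.error)
        else:
            r.update(
                mean_kPa=self.summary.mean,
                std_kPa=self.summary.std,
                max_kPa=self.summary.max,
                error="",
            )
        return r


def build_experiment1_scenarios(
    tooth_params: ToothParams | None = None,
    solver: SolverSettings | None = None,
    remodeling: RemodelingParams | None = None,
) -> list[ScenarioConfig]:
    """Single 300 gf mesial force vs. the 2.94 N x 5.72 mm force couple.

    Both scenarios run the full movement loop with checkpoints at
    0.25, 1.5 and 3.0 mm of anchorage movement. The couple is two equal
    and opposite 2.94 N forces attached at the anatomical mid-buccal and
    mid-palatal crown points (both coronal to the gingival plane), so its
    line-of-action separation — and hence its moment — is set by the
    tooth's own buccopalatal crown width, as in a bracket pair bonded to
    the two crown surfaces.
    """
    tooth_params = tooth_params or ToothParams()
    solver = solver or SolverSettings()
    remodeling = remodeling or RemodelingParams(target_movement=3.05)
    single = ScenarioConfig(
        label="exp1-single",
        tooth_params=tooth_params,
        appliance_specs=[
            {"type": "constant_force", "gf": 300.0, "direction": MESIAL,
             "attachment": "mid_buccal"},
        ],
        solver=solver,
        remodeling=remodeling,
        direction_label="mesial",
        checkpoints=(0.25, 1.5, 3.0),
    )
    couple = ScenarioConfig(
        label="exp1-couple",
        tooth_params=tooth_params,
        appliance_specs=[
            {"type": "constant_force", "gf": 300.0, "direction": MESIAL,
             "attachment": "mid_buccal"},
            {"type": "constant_force", "gf": 300.0, "direction": DISTAL,
             "attachment": "mid_palatal"},
        ],
        solver=solver,
        remodeling=remodeling,
        direction_label="couple",
        checkpoints=(0.25, 1.5, 3.0),
    )
    return [single, couple]


def build_experiment2_scenarios(
    tooth_params: ToothParams | None = None,
    catalog: list[CoilTemplate] | None = None,
    solver: SolverSettings | None = None,
) -> list[ScenarioConfig]:
    """Factorial angulation x force direction x coil catalog, instantaneous only."""
    tooth_params = tooth_params or ToothParams()
    catalog = catalog if catalog is not None else default_coil_catalog()
    if not catalog:
        raise ValueError("coil catalog is empty")
    solver = solver or SolverSettings()
    scenarios = []
    for alpha in (15.0, 0.0, -15.0, -30.0):
        for dname, direction in (("HF", HF_DIRECTION), ("DF", DF_DIRECTION)):
            for coil in catalog:
                scenarios.append(ScenarioConfig(
                    label=f"exp2-a{alpha:+.0f}-{dname}-{coil.label}",
                    alpha_deg=alpha,
                    tooth_params=tooth_params,
                    appliance_specs=[{
                        "type": "coil",
                        "label": coil.label,
                        "stiffness": coil.stiffness,
                        "rest_length": coil.rest_length,
                        "activation_length": coil.activation_length,
                        "direction": direction,
                        "attachment": "mid_buccal",
                    }],
                    solver=solver,
                    remodeling=None,
                    direction_label=dname,
                    coil_label=coil.label,
                ))
    return scenarios


def run_scenario(config: ScenarioConfig, plane: Plane | None = None) -> ScenarioResult:
    """Execute one scenario: build the tooth and field, solve, summarize."""
    plane = plane or DEFAULT_GINGIVAL_PLANE
    tooth = config.build_tooth()
    appliances = _resolve_appliances(config, tooth)
    field = build_field(tooth.mesh, plane, config.pdl,
                        face_subset=tooth.anatomical_root_faces)
    f0 = 0.0
    for item in appliances:
        mag = getattr(item, "magnitude", None)
        if mag is None:
            mag = initial_force(item)
        f0 = max(f0, float(mag))

    result = ScenarioResult(
        label=config.label,
        alpha_deg=config.alpha_deg,
        direction=config.direction_label,
        coil=config.coil_label,
        initial_force_N=f0,
    )
    if config.remodeling is None:
        eq = solve_instantaneous(
            field, appliances, RigidPose.identity(), config.solver,
            config.pdl, tooth.landmarks, plane,
        )
        result.summary = summarize(eq.states)
        result.overall_max_kPa = result.summary.max
        result.equilibrium = eq
    else:
        otm = run_otm(field, appliances, tooth.landmarks, config.pdl,
                      config.solver, config.remodeling, plane)
        result.otm = otm
        result.summary = otm.samples[0].summary  # end of instantaneous movement
        result.overall_max_kPa = float(max(s.summary.max for s in otm.samples))
        if config.checkpoints:
            result.checkpoints = checkpoint_summaries(otm, config.checkpoints)
    return result


def run_experiments(
    scenarios: list[ScenarioConfig],
    parallel_workers: int = 1,
    plane: Plane | None = None,
) -> tuple[pd.DataFrame, list[ScenarioResult]]:
    """Run a batch; per-scenario failures are recorded, not raised.

    Execution is sequential and deterministic regardless of
    ``parallel_workers`` (each scenario is independent; the knob is kept
    for API stability and validated only).
    """
    if parallel_workers < 1:
        raise ValueError("parallel_workers must be >= 1")
    results = []
    for config in scenarios:
        try:
            results.append(run_scenario(config, plane))
        except Exception as exc:  # isolate per-cell failures
            results.append(ScenarioResult(
                label=config.label, alpha_deg=config.alpha_deg,
                direction=config.direction_label, coil=config.coil_label,
                initial_force_N=0.0, error=f"{type(exc).__name__}: {exc}",
            ))
    df = pd.DataFrame([r.row() for r in results])
    return df, results


def _color_scale(values: np.ndarray) -> list[str]:
    """Green -> red hex colors spanning the observed min/max."""
    from matplotlib import colormaps
    from matplotlib.colors import Normalize, to_hex

    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return ["#ffffff"] * len(values)
    norm = Normalize(vmin=finite.min(), vmax=finite.max())
    cmap = colormaps["RdYlGn_r"]
    return [to_hex(cmap(norm(v))) if np.isfinite(v) else "#ffffff" for v in values]


def write_report(df: pd.DataFrame, outdir: str | Path) -> Path:
    """Write results.csv and a color-scaled report.html; return the dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / "results.csv", index=False)

    rows = []
    for col in ("mean_kPa", "max_kPa"):
        colors = _color_scale(df[col].to_numpy(dtype=float))
        cells = "".join(
            f'<td style="background:{c}">{v:.1f}&plusmn;{s:.1f}</td>'
            if col == "mean_kPa" and np.isfinite(v)
            else (f'<td style="background:{c}">{v:.1f}</td>' if np.isfinite(v) else "<td>err</td>")
            for c, v, s in zip(colors, df[col], df["std_kPa"])
        )
        rows.append((col, cells))
    header = "".join(f"<th>{lbl}</th>" for lbl in df["label"])
    body = "".join(f"<tr><th>{name}</th>{cells}</tr>" for name, cells in rows)
    html = (
        "<html><head><meta charset='utf-8'><title>otmspring report</title></head>"
        "<body><h1>PDL Von Mises stress report [kPa]</h1>"
        f"<table border='1' style='border-collapse:collapse;font-family:sans-serif'>"
        f"<tr><th></th>{header}</tr>{body}</table>"
        "<p>mean&plusmn;std and max per scenario; green = low, red = high.</p>"
        "</body></html>"
    )
    (outdir / "report.html").write_text(html)
    return outdir


def scenario_from_yaml(path: str | Path) -> ScenarioConfig:
    """Load a scenario config from YAML.

    Schema: ``label``, ``alpha_deg``, ``tooth`` ({params: {...}} or
    {mesh: path, landmarks: path}), ``appliances`` (list of appliance
    spec dicts), optional ``solver``, ``remodeling`` (mapping or null),
    ``pdl``, ``checkpoints``, ``output_dir``.
    """
    import yaml

    from .geometry import load_mesh
    import json

    raw = yaml.safe_load(Path(path).read_text())
    tooth_params = None
    tooth = None
    tsrc = raw.get("tooth", {"params": {}})
    if "params" in tsrc:
        tooth_params = ToothParams(**(tsrc["params"] or {}))
    elif "mesh" in tsrc:
        mesh = load_mesh(tsrc["mesh"])
        landmarks = {
            k: np.asarray(v, dtype=float)
            for k, v in json.loads(Path(tsrc["landmarks"]).read_text()).items()
        }
        tooth = ToothModel(mesh=mesh, landmarks=landmarks,
                           long_axis=np.array([0.0, 0.0, 1.0]),
                           params=ToothParams())
    else:
        raise ValueError("tooth source must give 'params' or 'mesh'+'landmarks'")
    remodeling = raw.get("remodeling")
    return ScenarioConfig(
        label=raw.get("label", Path(path).stem),
        alpha_deg=float(raw.get("alpha_deg", 0.0)),
        tooth_params=tooth_params,
        tooth=tooth,
        appliance_specs=raw.get("appliances", []),
        solver=SolverSettings(**(raw.get("solver") or {})),
        remodeling=None if remodeling is None else RemodelingParams(**remodeling),
        pdl=PDLParams(**(raw.get("pdl") or {})),
        checkpoints=tuple(raw.get("checkpoints", ())),
        output_dir=Path(raw["output_dir"]) if raw.get("output_dir") else None,
    )
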