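"""Shared fixtures: small synthetic teeth, spring fields, flat patches.

Expensive study-condition runs (the packaged experiments at default
resolution) are session-scoped so the acceptance tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import otmspring as om
from otmspring.geometry import DEFAULT_GINGIVAL_PLANE, TriMesh


#: reduced-resolution tooth for unit tests (544 faces)
SMALL = om.ToothParams(n_circ=16, n_axial_root=10, n_axial_crown=8)


@pytest.fixture(scope="session")
def pdl_params() -> om.PDLParams:
    return om.PDLParams()


@pytest.fixture(scope="session")
def small_tooth() -> om.ToothModel:
    return om.generate_canine(SMALL)


@pytest.fixture()
def small_field(small_tooth, pdl_params) -> om.SpringField:
    return om.build_field(
        small_tooth.mesh, DEFAULT_GINGIVAL_PLANE, pdl_params,
        face_subset=small_tooth.anatomical_root_faces,
    )


def flat_patch(n: int = 4, size: float = 2.0, z0: float = 5.0) -> TriMesh:
    """Square patch in the z = z0 plane with +z face normals.

    Lies apical to the canonical gingival plane, so a field built on it
    contains one block per face; useful for closed-form spring checks.
    """
    xs = np.linspace(0.0, size, n + 1)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z0)])
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b = a + 1
            c = a + (n + 1)
            d = c + 1
            faces.append((a, d, b))   # winding gives +z normals
            faces.append((a, c, d))
    return TriMesh(verts, np.asarray(faces))


@pytest.fixture()
def patch_field(pdl_params):
    mesh = flat_patch()
    field = om.build_field(mesh, DEFAULT_GINGIVAL_PLANE, pdl_params)
    return mesh, field


# --------------------------------------------------------------------
# study-condition runs shared by the acceptance tests (default canine)
# --------------------------------------------------------------------

@pytest.fixture(scope="session")
def experiment1_results():
    """Single-force and force-couple full movement runs."""
    from otmspring.experiments import build_experiment1_scenarios, run_scenario

    single, couple = build_experiment1_scenarios()
    return run_scenario(single), run_scenario(couple)


@pytest.fixture(scope="session")
def experiment2_table():
    """The 128-scenario instantaneous grid as a DataFrame."""
    from otmspring.experiments import build_experiment2_scenarios, run_experiments

    df, _ = run_experiments(build_experiment2_scenarios())
    return df
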