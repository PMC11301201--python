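# Methods

## The spring-block ligament model

The periodontal ligament (PDL) is a 0.15–0.38 mm soft-tissue layer
between root cementum and alveolar bone. Instead of meshing it
volumetrically, `otmspring` lumps it into independent spring blocks, one
per root-surface triangle: the tooth-side end is the face centroid and
moves rigidly with the tooth, the bone-side anchor starts one ligament
thickness `l0` outside the surface along the outward normal. Each block
carries a linear spring (stiffness `k_n = E·a/l0`) along its rest axis
and a shear spring (`k_s = G·a/l0`) for the tangential deformation
`l0·tan θ`. Area normalization makes the aggregate response
mesh-independent: the net reaction to a fixed displacement changes by
well under 2 % when the mesh resolution doubles, and for a flat patch
under pure normal displacement δ the total force is exactly
`(E·A/l0)·δ`.

Assumptions inherited from the ligament literature: linear isotropic
elasticity (`E = 0.68 MPa`, `ν = 0.45`, hence `G = E/2.9 ≈ 0.2345 MPa`),
uniform thickness `l0 = 0.265 mm`, quasi-static response. Viscoelastic,
anisotropic or spatially varying ligament behavior, hyalinization under
extreme compression, and interactions with neighboring teeth are out of
scope.

Stress reporting is per block: `σ = E·(l−l0)/l0`, `τ = G·tan θ`, and the
Von Mises equivalent `σ_vm = sqrt(σ² + 3τ²)` in kPa. Field summaries
(mean, max, std) are **area-weighted** by default — stiffness is
area-normalized, so the area-weighted mean is the surface-consistent
statistic — with a per-block unweighted option (`summarize(...,
area_weighted=False)`) since either convention appears in the
literature.

## Instantaneous movement (stage 1)

The tooth is rigid; its pose minimizes

```
U(pose) = Σ_active [ ½k_n(l−l0)² + ½k_s(l0 tanθ)² + barrier ] + Σ U_appliance
```

by backtracking (Armijo) gradient descent over six coordinates:
translation [mm] and a rotation increment about the field centroid,
expressed as radians × characteristic length so all coordinates share
units. The gradient is analytic and verified against central finite
differences (≤ 1e−5 relative). Defaults: gradient tolerance 1e−6 N,
energy-decrease tolerance 1e−12 N·mm, step grown ×1.6 after acceptance
and halved on rejection, max 50 000 iterations; non-convergence is
flagged on the result, not raised. The solver is deterministic —
identical inputs give bit-identical poses.

Numerical choices:

* **Shear measure.** The shear element is a tangential-displacement
  spring with energy `½k_s(l0 tanθ)²`, which reproduces `τ = G·tanθ`; the
  deformation decomposition uses the block's *rest* axis (fixed between
  remodeling updates), keeping the energy a smooth function of pose. A
  guard of 1e−9 mm in the `tanθ` denominator avoids division by zero at
  extreme compression.
* **Compression floor.** The ligament cannot be squeezed flat: once a
  block's normal projection drops below `c·l0` (default `c = 0.25`, a
  configuration parameter — no published value exists), a C¹ quadratic
  penalty with stiffness `10·k_n` (barrier multiplier, configurable)
  activates. Equilibrium projections stay within ~2 % of the floor.
* **Rotation parameterization.** Increments are applied on the left via
  the rotation exponential about the field centroid; steps are small, so
  parameterization singularities never arise.
* **Gum-line pruning during descent.** A block whose tooth-side point
  acquires positive signed distance to the gingival plane (occlusal
  side) is deactivated permanently. Removal deletes a non-negative
  energy term, so the accepted-step energy sequence stays
  non-increasing. The tooth-side point is used because it is the moving
  end of the fibre.

The solver was cross-checked against a dense 101×101 grid search on a
2-DOF restriction (x-translation + y-rotation): the descent equilibrium
falls within one grid cell of the grid minimum.

## Bone remodeling (stage 3)

A block strained beyond `ε_min = 1500 µstrain` (the classical minimum
for remodeling; gate applied to the normal strain `|l−l0|/l0`) drags its
anchor toward the position that restores rest geometry at the current
pose — `world(O) + l0·n_current` — at speed `η·σ_vm` [mm/step], capped
at 0.02 mm/step, with `η_res = 5e−4` on the compressed side (`σ < 0`)
and `η_form = 2.5e−4` mm/(kPa·step) on the tension side. Only the
direction dependence and the resorption-faster-than-formation asymmetry
are established; the linear rate law, the 2:1 ratio and the cap are
package defaults chosen so a 300 gf load advances ~0.01–0.02 mm per
cycle, and all assertions about remodeling are orderings, never absolute
rates. After a step the block's rest axis is re-derived from the new
anchor, so a fully relaxed block is again an undeformed normal spring.
One step is one abstract iteration: the model has no physical time
scale, and the biological latency phase between loading and remodeling
is not represented.

The movement loop alternates instantaneous solves with remodeling steps,
pruning after every accepted pose change, and stops when every appliance
force falls below `f_stop` (0.02 N), the per-cycle anchorage-movement
increment falls below `d_stop`, a target travel is reached, the cycle
cap (500) hits, or no block clears the strain gate. "Anchorage
movement" is the displacement of the first appliance's attachment point
from its initial world position (the tracked landmark is not fixed by
any published definition; the attachment is the natural clinical
choice). Checkpoint summaries take the first recorded sample at or
beyond each requested distance.

Observed behavior worth knowing: with the appliance *removed*, repeated
remodel/re-solve cycles relax the mean stress monotonically toward zero,
and a single-force (tipping) field relaxes *faster* than a couple field
at matched initial mean — the tipping field concentrates strain far
above the gate while the couple's shear field spreads it. During
treatment, with the appliance acting, the couple's mean stress declines
proportionally faster over the run, which is the sense in which couple
loading relaxes faster and the sense the test suite asserts.

## Appliances

* `ConstantForce`: dead load, `U = −F·x`; gram-force converts at
  `g = 9.8 m/s²` exactly so 300 gf ↔ 2.94 N.
* `CoilSpring`: `U = ½k(|x−anchor|−l_r)²`, placement force
  `F_i = k(l_l−l_r)`; at setup the world anchor is placed one activation
  length from the attachment along the requested force direction and is
  fixed thereafter, so the coil unloads (and its pull direction swings)
  as the tooth travels. Coil stiffness is assumed constant over the
  working range.
* A force couple is two opposite `ConstantForce` items; it contributes a
  pure moment (net generalized force < 1e−9 N at any pose).

The packaged coil catalog (`data/coil_catalog_synthetic.csv`) is a
**synthetic stand-in**: commercial closed-coil constants are not public,
so 16 templates over rest lengths {9, 12, 15} mm and stiffness classes
L/M/H (0.098/0.245/0.490 N/mm) were fixed so the Hooke's-law initial
forces span 1.96–7.84 N (200–800 gf) with 16 distinct values. Users can
supply their own CSV (`model_label, rest_length_mm, stiffness_N_per_mm,
activation_length_mm`).

## The synthetic canine

No patient geometry ships with the package; `generate_canine` builds a
watertight stand-in in a fixed frame (+z apical, −z occlusal, +x distal,
+y palatal; gingival plane z = 0 with occlusal normal −z): a tapered
elliptic root (profile `(1−u²)^(taper/2)`, default 16 mm long, 4 × 3.5 mm
base radii, taper 1.5) and a bulged crown (10 mm) closed at an incisal
tip. Ring radii carry the area-preserving polygon correction
`sqrt((2π/n)/sin(2π/n))`, making enclosed volume second-order accurate
(area and volume change < 0.5 % between the default ~2900-face
resolution and its double). Landmarks (apex, crown tip, mid-buccal and
mid-palatal crown points at half crown height) are mesh vertices.
Optional seeded radial jitter roughens the surface for robustness
studies; it defaults to 0.

Angulation rotates the tooth about the mesiodistal (x) axis through the
long-axis/gingival-plane intersection, leaving the plane fixed. PDL
blocks are restricted to the *anatomical root surface* (recorded at
generation) intersected with the apical side of the plane: the ligament
attaches to cementum, so a tilted, partially erupted tooth loses
coverage where the root emerges but never gains springs on enamel. This
restriction is what lets the peak stress grow at acute angulations (the
supported area shrinks asymmetrically); without it the submerged crown
props the tooth up and the angulation dependence inverts.

What the stand-in does *not* emulate: real canine cross-sections
(non-elliptic, with developmental grooves), curved roots, a non-planar
gingival margin, and patient-specific root surface area. Absolute kPa
values therefore differ from any patient case, and the test suite
asserts only orderings, oracle agreements and invariances — passing
tests show the mechanics and the remodeling logic are right, not that a
particular patient's stresses are predicted.

## Experiment harness

Experiment 1 compares a single 2.94 N mesial force at the mid-buccal
point against a force couple (equal and opposite 2.94 N forces at the
mid-buccal and mid-palatal crown points, i.e. a pure moment of 2.94 N ×
the crown's buccopalatal width there), both run through the remodeling
loop to 3 mm with checkpoints at 0.25/1.5/3.0 mm. Attaching the couple
at the anatomical crown points (rather than at an arbitrary bracket
separation) is the design choice that fixes its moment arm; the arm is
then a property of the tooth, as it is clinically.

Experiment 2 is the full factorial α ∈ {15, 0, −15, −30}° × direction
(HF = +x in the gingival plane; DF = (1,0,−1)/√2, 45° occlusal-ward —
both world-frame directions fixed by the plane, not the tooth) × the
16-coil catalog = 128 scenarios, instantaneous-only: heavy forces would
provoke tissue responses the remodeling stage does not model, so
stresses are recorded at the end of the instantaneous movement. Batches
run sequentially and deterministically; per-scenario failures are
recorded as error cells without aborting.

Problem sizes: the default canine has ~2900 faces (~1900 spring blocks);
a 128-scenario instantaneous batch takes ~20 s and a full 3 mm
remodeling run 10–30 s on one CPU. Unit tests use a ~540-face tooth.

## Known limitations

* No time scale: remodeling steps are abstract iterations; treatment
  duration cannot be read off the trajectories.
* Single tooth only; no archwire/bracket friction, no appliance property
  drift during treatment.
* The gingival boundary is a plane; intraoral-scan gum contours are not
  supported.
* The compression-floor fraction, barrier multiplier and remodeling rate
  constants are plausible defaults, not calibrated values; conclusions
  should rest on orderings and trends, as the shipped experiments do.
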