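"""Angulation x force-direction x coil grid (instantaneous stresses).

Runs a slice of the 128-scenario grid — every angulation and direction
with the lightest (200 gf) and heaviest (800 gf) packaged coils — and
prints the mean/max Von Mises stress table. Swap in the full catalog to
reproduce the complete grid.
"""

from otmspring.appliance import default_coil_catalog
from otmspring.experiments import build_experiment2_scenarios, run_experiments, write_report

catalog = [c for c in default_coil_catalog() if c.label in ("9-L", "9-H+")]
scenarios = build_experiment2_scenarios(catalog=catalog)
df, _ = run_experiments(scenarios)
table = df.pivot_table(index="coil", columns=["direction", "alpha_deg"],
                       values="mean_kPa").round(1)
print("mean Von Mises stress [kPa]:")
print(table)
write_report(df, "angulation_grid")
print("\nwrote angulation_grid/results.csv and report.html")
# Horizontal traction (HF) gives a higher mean than the 45-degree
# distal-occlusal pull (DF) at every angulation, and stress scales with
# the coil's Hooke's-law initial force far more than with its length or
# stiffness individually.
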