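"""The packaged coil catalog and Hooke's-law placement forces.

Lists the 16 synthetic coil templates (rest length, stiffness class,
activation) and the initial force F_i = k (l_l - l_r) each develops,
spanning 200-800 gf.
"""

from otmspring.appliance import default_coil_catalog, gram_force_to_newton

print(f"{'label':8s} {'rest':>6s} {'k':>7s} {'activation':>11s} {'F_init':>8s}")
for coil in sorted(default_coil_catalog(), key=lambda c: c.initial_force):
    print(f"{coil.label:8s} {coil.rest_length:5.0f}mm "
          f"{coil.stiffness:5.3f}N/mm {coil.activation_length:8.0f}mm "
          f"{coil.initial_force:6.2f} N")
print(f"\nrange check: 200 gf = {gram_force_to_newton(200):.2f} N, "
      f"800 gf = {gram_force_to_newton(800):.2f} N")
# Labels encode rest length and stiffness class (L/M/H), '+' marking a
# longer activation of the same coil; the constants are a documented
# synthetic stand-in for commercial closed-coil catalogs.
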