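"""Spring-force PMF between oppositely charged nanospheres, explicit ions.

Builds the |Z|=12e pair in 10 mM 2:2 salt, runs the tethered Metropolis
chains over a 7-point separation grid and integrates the mean spring forces
into the potential of mean force.
"""

from ionpmf import MCParams, SystemSpec, pmf_mc

spec = SystemSpec(Z=12, z=2, c0=0.01, x=22.0)
print(f"box side {spec.box[0]:.0f} A, {spec.n_ion_pairs()} salt pairs, "
      f"Debye length {spec.debye_len:.1f} A")

curve, forces, _ = pmf_mc(
    spec, MCParams(seed=1, n_production_sweeps=150_000),
    x_values=[22, 25, 28, 31, 34, 37, 40],
)

print(f"{'x (A)':>6} {'F (nN)':>10} {'dG (kBT)':>12}")
for f, dg, de in zip(forces, curve.dG, curve.dG_err):
    print(f"{f.x:6.0f} {f.F:+10.4f} {dg:+8.2f} +- {de:.2f}")

print("\nNegative F and dG mean attraction; the well deepens toward contact"
      "\n(x = 22 A) and vanishes at the 40 A reference by construction.")
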