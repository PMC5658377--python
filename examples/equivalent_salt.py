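"""How much 1:1 salt screens like a given 2:2 salt?

Uses the mean-field route (fast) to build a 1:1 ladder of PMF depths at
|Z|=9e, then interpolates the 10 mM 2:2 depth onto it.  Divalent ions are
far more efficient per mole: 10 mM 2:2 salt screens like ~80 mM 1:1 salt.
"""

from ionpmf import SystemSpec, pb_pmf, reduced_schedule
from ionpmf.observables import equivalent_salt

ladder_c = [0.01, 0.03, 0.1, 0.3]
dgs = []
for c0 in ladder_c:
    spec = SystemSpec(Z=9, z=1, c0=c0, x=22.0)
    curve, _ = pb_pmf(spec, reduced_schedule(spec, final_h=1.0),
                      x_values=[22.0, 40.0])
    dgs.append(float(curve.dG[0]))
    print(f"1:1 {1000 * c0:5.0f} mM : dG(22 A) = {dgs[-1]:+.2f} kBT")

spec22 = SystemSpec(Z=9, z=2, c0=0.01, x=22.0)
curve, _ = pb_pmf(spec22, reduced_schedule(spec22, final_h=1.0),
                  x_values=[22.0, 40.0])
target = float(curve.dG[0])
print(f"2:2    10 mM : dG(22 A) = {target:+.2f} kBT")

c_eq = equivalent_salt(ladder_c, dgs, target)
print(f"\nequivalent 1:1 concentration = {1000 * c_eq:.0f} mM")
print("(matching the PMF depth at x = 22 A; the binding profile Q(22 A) "
      "gives a similar map)")
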