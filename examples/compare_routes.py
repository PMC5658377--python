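"""The headline comparison: relative PMF deviation and the bound-ion gap.

Runs both routes for |Z|=12e in 10 mM 2:2 salt at x = 22 A and prints the
deviation statistics that quantify where mean-field theory breaks down.
"""

from ionpmf import MCParams, SystemSpec, pmf_mc
from ionpmf.observables import (
    compare,
    net_charge_fraction_mc,
    net_charge_fraction_pb,
)
from ionpmf.pb_solver import focusing_solve, pb_free_energy, reduced_schedule

spec = SystemSpec(Z=12, z=2, c0=0.01, x=22.0)
params = MCParams(seed=1, n_production_sweeps=300_000, snapshot_stride=100)

curve_mc, _, runs = pmf_mc(spec, params,
                           x_values=[22, 25, 28, 31, 34, 37, 40],
                           keep_runs_at=[22.0])
sched = reduced_schedule(spec, final_h=0.5)
lev22 = focusing_solve(spec, sched)
lev40 = focusing_solve(spec.at_separation(40.0), sched)
dg_pb = (pb_free_energy(lev22, spec)["total"]
         - pb_free_energy(lev40, spec.at_separation(40.0))["total"])

prof_mc = net_charge_fraction_mc(runs[22.0], spec)
prof_pb = net_charge_fraction_pb(lev22, spec)
report = compare(curve_mc.dG[0], dg_pb, prof_mc, prof_pb, spec.Z)

print(f"dG_MC(22 A) = {report.dG_mc:+.2f} ± {curve_mc.dG_err[0]:.2f} kBT   "
      f"dG_PB(22 A) = {report.dG_pb:+.2f} kBT")
print(f"ddg = {100 * report.ddg:.0f}%  (mean-field overestimation of the "
      "attraction)")
print(f"Q_MC(14 A) = {prof_mc.at(14.0):.3f}   Q_PB(14 A) = "
      f"{prof_pb.at(14.0):.3f}")
print(f"|Z| dQ* = {report.apparent:.2f}  (the apparent parameter that "
      "tracks ddg)")
print("\nThe explicit-ion route binds more divalent counterions than the "
      "mean field\npredicts; the missing bound charge is exactly what the "
      "mean field converts\ninto extra attraction.")
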