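# ionpmf

Potentials of mean force (PMFs) between two **oppositely charged
nanospheres** in symmetric 1:1 and 2:2 electrolytes, computed by two
independent routes over the same primitive model:

1. **Explicit-ion Monte Carlo** — canonical Metropolis sampling of charged
   hard spheres in a uniform dielectric, with the PMF from the
   *pseudo-spring* method: tether the particles with a stiff spring
   (k = 9 nN/Å), read the mean force from the mean extension,
   F(x) = k⟨Δx⟩, and integrate ΔG(x) = ∫ₓ^{40 Å} F(x′) dx′.
2. **Nonlinear Poisson–Boltzmann (PB) theory** — the mean-field equation
   ∇·[ε0ε∇ψ] = −(ρ_f + Σᵢ zᵢe cᵢ⁰ e^{−βzᵢeψ}) solved by finite differences
   with three-step grid focusing, and the PMF from the electrostatic free
   energy G_PB = ½∫Σcᵢzᵢe(ψ+ψ_f) + kBT∫Σ[c ln(c/c⁰) − c + c⁰] + U_NN.

The package is aimed at people studying ion-mediated interactions between
charged colloids and polyelectrolytes who want to know *when mean-field
electrostatics is quantitative*: it reproduces the result that PB is
accurate for monovalent salt (deviations of a few percent up to ~0.1 M)
but systematically **overestimates** the attraction in divalent salt —
by ~70% at x = 22 Å for |Z| = 24e in 10 mM 2:2 — because it underestimates
the strongly correlated bound divalent ions, a gap measured here by the
net bound ion charge fraction Q(r) and the apparent parameter |Z|ΔQ*(14 Å).

## Worked example

```python
from ionpmf import SystemSpec, MCParams, pmf_mc, pb_pmf, reduced_schedule
from ionpmf.observables import delta_delta_g

spec = SystemSpec(Z=12, z=2, c0=0.01, x=22.0)   # |Z|=12e, 10 mM 2:2 salt

curve_mc, forces, _ = pmf_mc(
    spec, MCParams(seed=1, n_production_sweeps=300_000),
    x_values=[22, 25, 28, 31, 34, 37, 40],
)
curve_pb, _ = pb_pmf(spec, reduced_schedule(spec, final_h=0.5),
                     x_values=[22, 40])
print(f"dG_MC(22 A) = {curve_mc.dG[0]:+.2f} +- {curve_mc.dG_err[0]:.2f} kBT")
print(f"dG_PB(22 A) = {curve_pb.dG[0]:+.2f} kBT")
print(f"ddg = {100 * delta_delta_g(curve_mc.dG[0], curve_pb.dG[0]):.0f}%")
```

prints (seed 1):

```
dG_MC(22 A) = -6.44 +- 0.36 kBT
dG_PB(22 A) = -8.46 kBT
ddg = 31%
```

i.e. at contact separation the explicit-ion attraction is ≈ 6.4 kBT deep
and the mean-field route overshoots it by ≈ 2 kBT.  The relative PMF
deviation ΔΔg fluctuates around ~17% at this reduced sampling (this seed
draws 31%; the ±0.36 kBT force-integral error propagates to roughly ±8
percentage points) — the divalent-salt overestimation at moderate charge
density, which grows to ~65% at |Z| = 24e.

More narrative walk-throughs live in `examples/`:

* `examples/mc_pmf.py` — spring-force PMF for one condition,
* `examples/pb_solver.py` — focused PB solve and its Debye–Hückel check,
* `examples/compare_routes.py` — ΔΔg and the bound-ion gap Q(r),
* `examples/equivalent_salt.py` — the 2:2 ↔ 1:1 equivalence map.

A thin CLI wraps the same calls: `ionpmf simulate|solve|compare|fixtures|plot`
(see `ionpmf --help`).

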