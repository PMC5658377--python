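# Methods

## The physical model

Two oppositely charged nanospheres (radius a = 10 Å, charges +Z e and −Z e
with Z ∈ {6, 9, 12, 18, 24}) sit at a centre-to-centre separation
x ∈ [22, 40] Å in a symmetric z:−z electrolyte (z = 1 or 2) whose ions are
charged hard spheres of radius 2 Å.  The solvent is a uniform dielectric
continuum, ε = 78; the dielectric discontinuity at the particle surface is
ignored.  All interactions are hard-core plus Coulomb,

    U_ij = q_i q_j lB / r_ij   (r_ij ≥ σ_i + σ_j),   +∞ otherwise,

with lB = e²/(4π ε0 ε kBT) the Bjerrum length.  Temperature is not a free
parameter of the study; we fix T = 298.15 K (room-temperature water implied
by ε = 78), giving lB ≈ 7.19 Å.  Internally all lengths are Å, energies
kBT, charges e; the only SI conversion points are `bjerrum_length` and the
nN·Å → kBT factor used by the force estimator (1 nN·Å ≈ 24.29 kBT).

The observable is the potential of mean force (PMF) ΔG(x) = G(x) − G(x_ref)
with x_ref = 40 Å, computed by two independent routes, and the deviation
statistics between them:

* ΔΔg = |(ΔG_MC(22 Å) − ΔG_PB(22 Å))/ΔG_MC(22 Å)|,
* the net bound ion charge fraction Q(r) = −(1/Z)∫_{<r} Σ z_i c_i d³r
  restricted to each particle's side of the bisector plane, and
* the apparent coupling parameter |Z|ΔQ* = |Z||Q_MC − Q_PB| at r = 14 Å.

## Route 1: explicit-ion Metropolis Monte Carlo

The canonical cell is a closed (hard-wall, non-periodic) cube; Coulomb sums
are direct over all pairs.  The cube side is x + 2a + 6λ_D — six
Debye–Hückel lengths of clearance beyond the particle surfaces, mirroring
the box rule used for the mean-field route — with a floor large enough that
the nominal salt content at least matches the binding demand Z/z of one
particle.

**Reservoir calibration.**  A closed cell cannot hold its bulk concentration
fixed: the bound layers around a ±24e pair can consume of order Z/z = 12–24
salt pairs, depleting the bulk by tens of percent and systematically
under-screening (hence over-binding the PMF).  Before each condition the
driver therefore runs short probe chains, measures the species concentration
in the region farther than 2.5 λ_D from both exclusion surfaces, and tops up
the reservoir in integer pairs until the far field matches c0 (3 rounds of
~20k sweeps; the correction is reused across separation windows because the
bound populations barely depend on x).  With the calibrated reservoir the
PMF is independent of further box enlargement within statistical error —
verified explicitly at |Z| = 24e, 10 mM 2:2 by comparing cells of 133 Å and
181–290 Å side.

**Moves.**  One sweep attempts one displacement per ion plus one axial
displacement of the tethered nanoparticle.  Ion proposals are local cubic
steps, except that a fixed fraction (20%) are re-insertion "jump" moves
drawn from a mixture density: half uniform over the cell, half uniform in
24 Å spheres centred on the two nanoparticle sites, accepted with the
Metropolis–Hastings ratio min(1, e^{−βΔU} q(old)/q(new)) so detailed
balance is exact (verified by the uniform-density oracle with neutral hard
spheres and the targeted proposals active).  The targeted component is what
makes the bound/bulk ion exchange ergodic in practice: with purely uniform
re-insertions the probability of proposing into the thin bound shell scales
as shell volume over cell volume (~5·10⁻⁵ in a 0.1 mM cell), leaving
bound-population relaxation times of thousands of sweeps and
under-converged, seed-scattered PMFs; with the mixture the spring-extension
autocorrelation time falls to ~10 sweeps at every condition studied and
independent seeds agree within their block-average error bars.  Local step
sizes are tuned toward ~40% acceptance during equilibration only, then
frozen.  Moves that would overlap a hard core or leave the cell are
rejected.

**Force and PMF.**  One particle is frozen; the other moves only along the
axis under a stiff tether of k = 9 nN/Å (≈ 218.6 kBT/Å²) with rest length
x.  The mean force is F(x) = k⟨Δx⟩ with Δx = d − x, so attraction
(compressed spring) gives F < 0; the instantaneous Δx fluctuates with
std √(kBT/k) ≈ 0.068 Å, which sets the sampling cost.  Errors come from
block averages (20 blocks).  ΔG(x) is the trapezoidal integral of F from x
to 40 Å; the default grid is x = 22, 24, …, 40 Å, and the reduced grids used
by the test suite and the acceptance script (5-8 windows) change
ΔG(22 Å) by ~1–3%, well inside the statistical error at those scales.

## Route 2: nonlinear Poisson–Boltzmann finite differences

In reduced units (u = βeψ) the equation is ∇²u = −4π lB [ρ_f/e − 2 z n0
a(r) sinh(z u)] with the fixed charge of each nanoparticle a central point
charge partitioned trilinearly onto its eight surrounding nodes (exact for
the exterior field of a uniformly charged sphere), and a(r) the ion
accessibility: zero within a + 2 Å = 12 Å of either centre (one-ion-radius
exclusion layer).  Discretization is the 7-point stencil; the solver is
red–black successive over-relaxation with a per-node Newton step on the
sinh term, ω from the Jacobi spectral-radius estimate, ten plain
Gauss–Seidel warm-up sweeps, Newton updates clamped to ±5 kBT/e, and the
sinh argument clamped to ±60 for overflow safety.  Iteration stops when the
largest per-sweep change falls below 1e-4 kBT/e.

**Focusing.**  Level 1 covers the particle surfaces plus 6 λ_D per side
(coarse spacing, ≈ 96 nodes along the longest side, so the resolution adapts
to concentration) with Debye–Hückel superposition boundary values and
initial guess.  Finer levels take Dirichlet faces and initial interiors by
trilinear interpolation from their parent.  The production schedule follows
the three-step ladder (160, 120, 120) Å at 1.0 Å then (100, 60, 60) Å at
0.25 Å; routine work and the shipped tests use a reduced schedule with a
final level of (100, 60, 60) Å at 0.5 or 1.0 Å — ΔG_PB(22 Å) for
|Z| = 24e, 10 mM 2:2 moves by under 1% between 1.0 and 0.25 Å final
spacing because the discretization error largely cancels between the x and
x_ref solves on geometrically identical grids.

**Free energy.**  Using reciprocity, ½∫ρ_f ψ splits into the (divergent but
x-independent, hence dropped) fixed self-energies, the analytic fixed–fixed
Coulomb term U_NN = −Z² lB/x, and ½∫ρ_ion ψ_f; the reported functional is

    G_PB = ½∫ Σ c_i z_i (u + u_f) + ∫ Σ [c_i ln(c_i/c0) − c_i + c0] + U_NN

with c_i = c0 e^{∓z u} on accessible nodes and zero on excluded nodes
(their constant c0 entropy offset is x-independent and dropped), and u_f
the potential solved on the same discrete operator with the ion term zeroed
— not the analytic Coulomb form — so that grid artifacts cancel inside the
first integral.  Integrals use midpoint (node × h³) quadrature on the finest
level plus each coarser level on the complement of its child box.  For
λ_D > 30 Å the reduced schedule inserts an intermediate (240, 180, 180) Å
level so the far ion cloud is not left to the very coarse level-1 mesh.

Validation: the solved field for a |Z| = 1e sphere in 10 mM 1:1 matches the
linearized Debye–Hückel closed form to 0.2% on r ∈ [14, 30] Å (tolerance
3%); ΔG_PB(x) at |Z| = 1e matches the DLVO-style screened pair form
−Z²lB e^{−κ(x−2b)}/[x(1+κb)²] (b = 12 Å) to ~2.5% (tolerance 10%); the
probe-point discretization error Richardson-extrapolates with order ≈ 2.

## Deviation statistics

Q(r) is accumulated in 0.5 Å bins from the instantaneous bisector plane
(MC) or the node fields (PB), for both particles, and averaged — the two
profiles are charge conjugates and their difference is reported as a
symmetry diagnostic.  The equivalent-salt map interpolates piecewise
linearly in (log10 c0, observable) and refuses to extrapolate.  The map can
be built from ΔG(22 Å) or from Q(22 Å; three ion layers); the shipped test
uses the binding observable for the explicit-ion route because a counting
statistic reaches useful precision ~10× faster than a force integral at
equal CPU cost, and cross-checks the PMF-based map with the mean-field
route, where both land at ≈ 0.08 M 1:1 for 10 mM 2:2 at |Z| = 9e.

## Problem sizes and statistical expectations

A production-quality PMF point at these conditions needs a few 10⁶ sweeps
per window; the package defaults and the shipped scripts use
10⁵–4·10⁵ production sweeps per window on 5–7 window grids, giving
σ(ΔG(22 Å)) ≈ 0.5–1.2 kBT.  The deviation percentages inherit this noise:
ΔΔg carries a standard error of ~3–9 percentage points depending on the
condition (largest where |ΔG_MC| is small, i.e. high 1:1 salt).  The
reference deviation ladder is reproduced within those widths; individual
reduced-sampling draws of the high-salt 1:1 deviation can wander a few
points around the expectation.

## What the model does and does not capture

The explicit-ion route captures ion–ion correlation and exclusion-volume
physics that mean-field theory lacks; both routes share the same primitive
model, so the comparison isolates exactly the mean-field approximation.
Neither route includes dielectric discontinuity or image charges, solvent
granularity, ion polarizability, charge regulation of the particle charge,
or asymmetric salts; separations far beyond the particle size are out of
scope.  Passing tests therefore demonstrate internal consistency of the two
routes and reproduction of the reference deviation statistics for this
model — not agreement with any particular experimental colloid system.

## Known limitations

* The canonical-cell reservoir calibration holds the far field at c0 to
  ~±1 pair; at very high salt the far-field probe volume is small and the
  calibration noise contributes ~1–2% to ΔG.
* The trapezoid force grid under-resolves the PMF curvature below ~2 Å
  spacing at 0.3 M (λ_D ≈ 5.6 Å); the residual bias is ≲3% at the reduced
  grids and noted where it matters.
* SOR with per-node Newton is robust for |Z| ≤ 24e at these conditions but
  is not a multigrid method; very fine production grids take minutes per
  solve.
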