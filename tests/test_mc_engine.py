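"""Metropolis sampling, the pseudo-spring force estimator, and PMF
integration."""

import math

import numpy as np
import pytest

from ionpmf.mc_engine import (
    ForceSample,
    MCParams,
    convergence_report,
    estimate_force,
    integrate_pmf,
    run_chain,
)
from ionpmf.model_core import (
    Configuration,
    InvalidParameterError,
    SystemSpec,
    build_system,
    nn_angstrom_to_kbt,
    spring_constant_kbt,
)
from ionpmf.orchestration import make_fixture


class TestEstimateForce:
    def test_constant_series(self):
        f = estimate_force(np.full(100, 0.01), 9.0, 20, x=22.0)
        assert f.F == pytest.approx(0.09)
        assert f.stderr_F == 0.0

    def test_zero_series(self):
        f = estimate_force(np.zeros(100), 9.0, 20)
        assert f.F == 0.0

    def test_gaussian_series_sampling_theory(self, rng):
        n = 40_000
        mu, sigma = 0.02, 0.068
        series = rng.normal(mu, sigma, n)
        f = estimate_force(series, 9.0, 20)
        assert abs(f.F - 9.0 * mu) < 3 * f.stderr_F
        assert f.stderr_F == pytest.approx(9.0 * sigma / math.sqrt(n),
                                           rel=0.3)

    def test_empty_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            estimate_force(np.array([]), 9.0, 20)


def fs(x, F, err=0.0):
    return ForceSample(x=x, mean_dx=F / 9.0, F=F, stderr_F=err, n_samples=1)


class TestIntegratePMF:
    def test_zero_force_zero_pmf(self):
        curve = integrate_pmf([fs(x, 0.0) for x in range(22, 41, 2)], 40.0)
        assert np.all(curve.dG == 0.0)

    def test_constant_force(self):
        c = -0.09
        curve = integrate_pmf([fs(float(x), c) for x in range(22, 41, 2)],
                              40.0)
        assert curve.dG[-1] == 0.0
        assert curve.dG[0] == pytest.approx(c * 18.0 * nn_angstrom_to_kbt())

    def test_linear_force_exact(self):
        # trapezoid is exact for linear integrands
        a, b = 0.004, -0.25
        xs = np.arange(22.0, 41.0, 2.0)
        curve = integrate_pmf([fs(x, a * x + b) for x in xs], 40.0)
        conv = nn_angstrom_to_kbt()
        for x, dg in zip(xs, curve.dG):
            exact = (a / 2 * (40.0**2 - x**2) + b * (40.0 - x)) * conv
            assert dg == pytest.approx(exact, rel=1e-12, abs=1e-12)

    def test_error_propagation_in_quadrature(self):
        xs = np.arange(22.0, 41.0, 2.0)
        curve = integrate_pmf([fs(x, -0.1, err=0.01) for x in xs], 40.0)
        assert curve.dG_err[-1] == 0.0
        assert np.all(np.diff(curve.dG_err[::-1]) >= 0)

    def test_rejects_bad_grids(self):
        with pytest.raises(InvalidParameterError):
            integrate_pmf([fs(24.0, 0.0), fs(22.0, 0.0)], 40.0)
        with pytest.raises(InvalidParameterError):
            integrate_pmf([fs(22.0, 0.0), fs(22.0, 0.0)], 40.0)
        with pytest.raises(InvalidParameterError):
            integrate_pmf([fs(22.0, 0.0), fs(30.0, 0.0)], 40.0)


class TestConvergenceReport:
    def test_stationary_series_converged(self, rng):
        rep = convergence_report(22.0 + rng.normal(0, 0.07, 20_000))
        assert rep["converged"]

    def test_drifting_series_not_converged(self, rng):
        s = 22.0 + np.linspace(0, 0.5, 20_000) + rng.normal(0, 0.01, 20_000)
        assert not convergence_report(s)["converged"]

    def test_ar1_series_against_generating_mean(self, rng):
        # AR(1) with known stationary mean: split-half flag should accept
        phi, mu = 0.95, 22.0
        n = 50_000
        eps = rng.normal(0, 0.02, n)
        s = np.empty(n)
        s[0] = mu
        for i in range(1, n):
            s[i] = mu + phi * (s[i - 1] - mu) + eps[i]
        rep = convergence_report(s)
        assert rep["converged"]
        assert abs(np.mean(rep["half_means"]) - mu) < 0.01


class TestChainPhysics:
    def test_spring_only_equipartition(self):
        fx = make_fixture("spring_only")
        cfg = fx["config"]
        spec = SystemSpec(Z=0, z=1, c0=1e-4, x=fx["x_rest"],
                          box=cfg.cell.copy(), validate_box=False)
        run = run_chain(cfg, spec,
                        MCParams(n_equilibration_sweeps=4000,
                                 n_production_sweeps=60_000, seed=5,
                                 snapshot_stride=0))
        dx = run.dx_series
        assert dx.std() == pytest.approx(fx["expected"]["dx_std"], rel=0.05)
        assert abs(dx.mean()) < 3 * dx.std() / math.sqrt(len(dx) / 50)

    def test_ideal_gas_uniform_density(self):
        fx = make_fixture("ideal_gas")
        cfg = fx["config"]
        spec = SystemSpec(Z=0, z=1, c0=1e-4, x=22.0, box=cfg.cell.copy(),
                          validate_box=False)
        run = run_chain(cfg, spec,
                        MCParams(n_equilibration_sweeps=2000,
                                 n_production_sweeps=40_000, seed=2,
                                 snapshot_stride=20),
                        spring=False)
        # occupancy of the left half-box: binomial around p=1/2 over the
        # accessible slab (centres range 2..38 per axis)
        snaps = run.snapshots
        frac = (snaps[:, :, 0] < 20.0).mean()
        n_eff = snaps.shape[0] * snaps.shape[1] / 40  # correlation margin
        assert abs(frac - 0.5) < 3 / math.sqrt(n_eff) + 0.01

    def test_one_ion_density_matches_boltzmann_quadrature(self):
        fx = make_fixture("one_ion")
        cfg = fx["config"]
        spec = SystemSpec(Z=2, z=2, c0=1e-4, x=22.0, box=cfg.cell.copy(),
                          validate_box=False)
        run = run_chain(cfg, spec,
                        MCParams(n_equilibration_sweeps=5000,
                                 n_production_sweeps=150_000, seed=8,
                                 snapshot_stride=10),
                        spring=False)
        r_edges = np.array([12.0, 14.0, 16.0, 18.0, 21.0, 26.0, 40.0])
        d = np.linalg.norm(run.snapshots[:, 1, :] - cfg.positions[0], axis=1)
        counts, _ = np.histogram(d, bins=r_edges)
        p_mc = counts / counts.sum()
        p_oracle = fx["oracle"](r_edges, spec.bjerrum)
        n_eff = len(d) / 100  # generous correlation allowance
        for pm, po in zip(p_mc, p_oracle):
            se = math.sqrt(max(po * (1 - po), 1e-6) / n_eff)
            assert abs(pm - po) < 4 * se + 0.01

    def test_seeded_determinism(self):
        spec = SystemSpec(Z=6, z=1, c0=0.1, x=22.0)
        cfg = build_system(spec, 4)
        params = MCParams(n_equilibration_sweeps=500,
                          n_production_sweeps=2000, seed=99)
        a = run_chain(cfg, spec, params)
        b = run_chain(cfg, spec, params)
        assert np.array_equal(a.dx_series, b.dx_series)
        assert np.array_equal(a.configuration.positions,
                              b.configuration.positions)

    def test_evolved_configuration_invariants(self):
        spec = SystemSpec(Z=6, z=2, c0=0.02, x=22.0)
        cfg = build_system(spec, 4)
        run = run_chain(cfg, spec, MCParams(n_equilibration_sweeps=2000,
                                            n_production_sweeps=5000,
                                            seed=1, snapshot_stride=0))
        out = run.configuration
        assert out.net_charge() == 0.0
        assert np.all(out.positions >= out.radii[:, None] - 1e-9)
        assert np.all(out.positions <= out.cell - out.radii[:, None] + 1e-9)
        # no hard-core overlap anywhere
        from scipy.spatial.distance import pdist

        r = pdist(out.positions)
        sig = out.radii[:, None] + out.radii[None, :]
        iu = np.triu_indices(out.n, k=1)
        assert np.all(r >= sig[iu] - 1e-9)

    def test_detailed_balance_two_state_toy(self, rng):
        # the Metropolis rule used by the chain, exercised on a 2-state
        # system: empirical flows satisfy pi_i P_ij = pi_j P_ji
        du = 1.3
        state, n01, n10, occ0 = 0, 0, 0, 0
        for _ in range(200_000):
            if state == 0:
                occ0 += 1
                if rng.random() < math.exp(-du):
                    state = 1
                    n01 += 1
            else:
                state = 0
                n10 += 1
        flow01 = n01 / 200_000
        flow10 = n10 / 200_000
        assert flow01 == pytest.approx(flow10, rel=0.05)
        assert occ0 / 200_000 == pytest.approx(1 / (1 + math.exp(-du)),
                                               rel=0.02)
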