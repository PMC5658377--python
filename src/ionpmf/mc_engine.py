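"""Canonical Metropolis Monte Carlo of the primitive model and PMF estimation
by the pseudo-spring method.

One nanoparticle is frozen; the other is tethered to it by a stiff harmonic
spring of rest length x (the nominal separation) and may move only along the
x axis.  At equilibrium the mean spring extension <Δx> measures the mean force
between the particles, F(x) = k <Δx> (negative = attraction with the
convention Δx = <d> − x), and the PMF follows by integrating F from x up to
the reference separation x_ref = 40 Å where the interaction is taken as zero:

    ΔG(x) = ∫_x^{x_ref} F(x') dx'.

Moves are sequential single-sphere displacements (one attempt per mobile
sphere per sweep) with Metropolis acceptance min(1, exp(-βΔU)); ΔU includes
all Coulomb pair terms, hard-core exclusion, the hard cell walls, and the
spring energy ½k(d − x)².  Step sizes are auto-tuned toward ~40% acceptance
during equilibration and frozen for production, preserving detailed balance
where it matters.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numba
import numpy as np

from .model_core import (
    Configuration,
    InvalidParameterError,
    SystemSpec,
    build_system,
    nn_angstrom_to_kbt,
)

__all__ = [
    "MCParams",
    "ForceSample",
    "PMFCurve",
    "MCRun",
    "run_chain",
    "estimate_force",
    "integrate_pmf",
    "convergence_report",
    "calibrate_reservoir",
    "pmf_mc",
]

_SEED_MASK = 0x7FFFFFFF

MODE_FROZEN = 0
MODE_AXIAL = 1
MODE_FREE = 2


@dataclasses.dataclass
class MCParams:
    """Numerical knobs of a Monte Carlo run (all engineering choices; the
    physics is fixed by :class:`~ionpmf.model_core.SystemSpec`)."""

    n_equilibration_sweeps: int = 20_000
    n_production_sweeps: int = 200_000
    ion_max_step: float = 4.0  # Å, tuned during equilibration
    np_max_step: float = 0.15  # Å, axial step of the tethered nanoparticle
    seed: int = 0
    block_count: int = 20
    snapshot_stride: int = 100  # sweeps between stored ion snapshots
    tune_interval: int = 500
    #: fraction of ion moves proposed as re-insertions ("jump" moves); these
    #: decorrelate the slowly exchanging bound/bulk ion populations that
    #: local steps cross rarely
    jump_fraction: float = 0.2
    #: fraction of jump moves drawn from spheres of ``jump_bias_radius``
    #: around the nanoparticle sites instead of the whole cell
    #: (Metropolis-Hastings mixture proposal; essential in large dilute
    #: cells where a uniform jump almost never hits the bound shell)
    jump_bias: float = 0.5
    jump_bias_radius: float = 24.0  # Å
    #: attempts on the tethered nanoparticle per sweep (each costs O(N) like
    #: a single ion move); the default matches the standard one-attempt-per-
    #: mobile-sphere sweep
    np_attempts_per_sweep: int = 1

    def __post_init__(self) -> None:
        if self.n_equilibration_sweeps <= 0 or self.n_production_sweeps <= 0:
            raise InvalidParameterError("sweep counts must be positive")
        if self.ion_max_step <= 0 or self.np_max_step <= 0:
            raise InvalidParameterError("step sizes must be positive")
        if self.block_count <= 0:
            raise InvalidParameterError("block_count must be positive")


@dataclasses.dataclass
class ForceSample:
    """Spring-force estimate at one separation.

    F = k <Δx> in nN, with Δx = <d> − x so that attraction (spring compressed)
    gives F < 0 and the integrated PMF is negative.
    """

    x: float  # Å
    mean_dx: float  # Å
    F: float  # nN
    stderr_F: float  # nN
    n_samples: int


@dataclasses.dataclass
class PMFCurve:
    """ΔG(x) relative to x_ref for one method."""

    x_values: np.ndarray  # Å, ascending
    dG: np.ndarray  # kBT
    dG_err: np.ndarray  # kBT
    method: str  # {"MC", "PB"}
    x_ref: float

    def interp(self, x: float) -> float:
        return float(np.interp(x, self.x_values, self.dG))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"x_A": self.x_values, "dG_kT": self.dG, "dG_err": self.dG_err,
             "method": self.method}
        )


@dataclasses.dataclass
class MCRun:
    """Raw output of one Metropolis chain."""

    dx_series: np.ndarray  # Å, one value per production sweep (d - x_rest)
    snapshots: np.ndarray  # (S, N, 3) positions at the snapshot stride
    acceptance_ion: float
    acceptance_np: float
    ion_step: float
    np_step: float
    warnings: list
    configuration: Configuration  # final state


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

@numba.njit(cache=True, fastmath=True)
def _mc_kernel(pos, q, sig, cell, move_mode, lb, k_spring, x_rest,
               n_sweeps, ion_step_in, np_step_in, jump_fraction, np_attempts,
               jump_bias, bias_r, bias_c0x, bias_c1x, bias_cy, bias_cz,
               tune, tune_interval,
               dx_out, snap_stride, snap_out, seed):  # pragma: no cover
    np.random.seed(seed)
    n = pos.shape[0]
    ion_step = ion_step_in
    np_step = np_step_in
    max_step = min(cell[0], min(cell[1], cell[2])) / 4.0
    acc_ion = 0
    att_ion = 0
    acc_np = 0
    att_np = 0
    w_acc_ion = 0
    w_att_ion = 0
    w_acc_np = 0
    w_att_np = 0
    snap_count = 0
    # pair caches: distances, charge products (×lB), contact distances
    dist = np.empty((n, n))
    qq = np.empty((n, n))
    sig2 = np.empty((n, n))
    for i in range(n):
        dist[i, i] = 0.0
        for j in range(n):
            if j != i:
                ax = pos[i, 0] - pos[j, 0]
                ay = pos[i, 1] - pos[j, 1]
                az = pos[i, 2] - pos[j, 2]
                dist[i, j] = math.sqrt(ax * ax + ay * ay + az * az)
            qq[i, j] = q[i] * q[j] * lb
            sig2[i, j] = sig[i] + sig[j]
    rnew = np.empty(n)
    axial_idx = -1
    for i in range(n):
        if move_mode[i] == MODE_AXIAL:
            axial_idx = i
            break
    for sweep in range(n_sweeps):
        n_moves = n + (np_attempts - 1 if axial_idx >= 0 else 0)
        for imv in range(n_moves):
            if imv < n:
                i = imv
            else:
                i = axial_idx
            m = move_mode[i]
            if m == MODE_FROZEN:
                continue
            axial = m == MODE_AXIAL
            step = np_step if axial else ion_step
            ox = pos[i, 0]
            oy = pos[i, 1]
            oz = pos[i, 2]
            si = sig[i]
            jump = False
            if axial:
                nx = ox + (2.0 * np.random.random() - 1.0) * step
                ny = oy
                nz = oz
                att_np += 1
                w_att_np += 1
            else:
                if jump_fraction > 0.0 and np.random.random() < jump_fraction:
                    # re-insertion from a mixture: uniform over the cell, or
                    # uniform in a sphere around one nanoparticle site; the
                    # Hastings ratio q(old)/q(new) restores detailed balance
                    jump = True
                    if jump_bias > 0.0 and np.random.random() < jump_bias:
                        bcx = bias_c0x if np.random.random() < 0.5 else bias_c1x
                        while True:
                            ux = 2.0 * np.random.random() - 1.0
                            uy = 2.0 * np.random.random() - 1.0
                            uz = 2.0 * np.random.random() - 1.0
                            if ux * ux + uy * uy + uz * uz <= 1.0:
                                break
                        nx = bcx + bias_r * ux
                        ny = bias_cy + bias_r * uy
                        nz = bias_cz + bias_r * uz
                    else:
                        nx = si + np.random.random() * (cell[0] - 2.0 * si)
                        ny = si + np.random.random() * (cell[1] - 2.0 * si)
                        nz = si + np.random.random() * (cell[2] - 2.0 * si)
                else:
                    nx = ox + (2.0 * np.random.random() - 1.0) * step
                    ny = oy + (2.0 * np.random.random() - 1.0) * step
                    nz = oz + (2.0 * np.random.random() - 1.0) * step
                if not jump:
                    att_ion += 1
                    w_att_ion += 1
            if (nx < si or nx > cell[0] - si or ny < si or ny > cell[1] - si
                    or nz < si or nz > cell[2] - si):
                continue
            du = 0.0
            ok = True
            for j in range(n):
                if j == i:
                    continue
                ax = nx - pos[j, 0]
                ay = ny - pos[j, 1]
                az = nz - pos[j, 2]
                rn = math.sqrt(ax * ax + ay * ay + az * az)
                if rn < sig2[i, j]:
                    ok = False
                    break
                rnew[j] = rn
                du += qq[i, j] * (1.0 / rn - 1.0 / dist[i, j])
            if not ok:
                continue
            if k_spring > 0.0 and i <= 1:
                jo = 1 - i
                dn = rnew[jo]
                do = dist[i, jo]
                du += 0.5 * k_spring * ((dn - x_rest) ** 2 - (do - x_rest) ** 2)
            log_ratio = -du
            if jump and jump_bias > 0.0:
                # mixture proposal density at old and new positions
                v_ins = ((cell[0] - 2.0 * si) * (cell[1] - 2.0 * si)
                         * (cell[2] - 2.0 * si))
                v_ball = 4.0 / 3.0 * math.pi * bias_r ** 3
                r2b = bias_r * bias_r
                nb_new = 0
                nb_old = 0
                for bidx in range(2):
                    bcx = bias_c0x if bidx == 0 else bias_c1x
                    ax = nx - bcx
                    ay = ny - bias_cy
                    az = nz - bias_cz
                    if ax * ax + ay * ay + az * az <= r2b:
                        nb_new += 1
                    bx = ox - bcx
                    by = oy - bias_cy
                    bz = oz - bias_cz
                    if bx * bx + by * by + bz * bz <= r2b:
                        nb_old += 1
                q_new = (1.0 - jump_bias) / v_ins \
                    + jump_bias * nb_new / (2.0 * v_ball)
                q_old = (1.0 - jump_bias) / v_ins \
                    + jump_bias * nb_old / (2.0 * v_ball)
                log_ratio += math.log(q_old / q_new)
            if log_ratio >= 0.0 or np.random.random() < math.exp(log_ratio):
                pos[i, 0] = nx
                pos[i, 1] = ny
                pos[i, 2] = nz
                for j in range(n):
                    if j != i:
                        dist[i, j] = rnew[j]
                        dist[j, i] = rnew[j]
                if axial:
                    acc_np += 1
                    w_acc_np += 1
                elif not jump:
                    acc_ion += 1
                    w_acc_ion += 1
        if k_spring > 0.0:
            ax = pos[1, 0] - pos[0, 0]
            ay = pos[1, 1] - pos[0, 1]
            az = pos[1, 2] - pos[0, 2]
            dx_out[sweep] = math.sqrt(ax * ax + ay * ay + az * az) - x_rest
        if snap_stride > 0 and (sweep + 1) % snap_stride == 0 \
                and snap_count < snap_out.shape[0]:
            for ii in range(n):
                snap_out[snap_count, ii, 0] = pos[ii, 0]
                snap_out[snap_count, ii, 1] = pos[ii, 1]
                snap_out[snap_count, ii, 2] = pos[ii, 2]
            snap_count += 1
        if tune and (sweep + 1) % tune_interval == 0:
            if w_att_ion > 0:
                rate = w_acc_ion / w_att_ion
                fac = rate / 0.4
                if fac < 0.5:
                    fac = 0.5
                if fac > 2.0:
                    fac = 2.0
                ion_step = min(max(ion_step * fac, 0.02), max_step)
            if w_att_np > 0:
                rate = w_acc_np / w_att_np
                fac = rate / 0.4
                if fac < 0.5:
                    fac = 0.5
                if fac > 2.0:
                    fac = 2.0
                np_step = min(max(np_step * fac, 0.005), max_step)
            w_acc_ion = 0
            w_att_ion = 0
            w_acc_np = 0
            w_att_np = 0
    rate_ion = acc_ion / att_ion if att_ion > 0 else 1.0
    rate_np = acc_np / att_np if att_np > 0 else 1.0
    return ion_step, np_step, rate_ion, rate_np, snap_count


def _move_modes(cfg: Configuration, spring: bool) -> np.ndarray:
    modes = np.full(cfg.n, MODE_FREE, dtype=np.int64)
    np_idx = [i for i, k in enumerate(cfg.kinds) if k == "nanoparticle"]
    for rank, i in enumerate(np_idx):
        if rank == 0:
            modes[i] = MODE_FROZEN
        elif rank == 1 and spring:
            modes[i] = MODE_AXIAL
        else:
            modes[i] = MODE_FROZEN
    return modes


def run_chain(cfg: Configuration, spec: SystemSpec, params: MCParams,
              spring: bool = True, move_mode: np.ndarray | None = None) -> MCRun:
    """Run equilibration (with step tuning) then production on a copy of
    ``cfg`` and return the production time series.

    ``move_mode`` overrides the default mobility assignment (frozen first
    nanoparticle, axially tethered second, free ions); used by fixtures.
    """
    work = cfg.copy()
    modes = _move_modes(work, spring) if move_mode is None else \
        np.asarray(move_mode, dtype=np.int64)
    k_spring = spec.k_spring_kbt if spring else 0.0
    lb = spec.bjerrum
    # targeted-jump geometry: spheres around the nominal nanoparticle sites
    np_idx = [i for i, k in enumerate(work.kinds) if k == "nanoparticle"]
    if len(np_idx) == 2 and params.jump_bias > 0.0:
        jump_bias = params.jump_bias
        c0 = work.positions[np_idx[0]]
        c1 = work.positions[np_idx[1]]
        bias_c0x, bias_c1x = float(c0[0]), float(c1[0])
        bias_cy, bias_cz = float(c0[1]), float(c0[2])
    else:
        jump_bias = 0.0
        bias_c0x = bias_c1x = bias_cy = bias_cz = 0.0
    bias_r = params.jump_bias_radius
    seed_eq = (int(params.seed) * 2654435761 + 17) & _SEED_MASK
    seed_pr = (int(params.seed) * 2654435761 + 9173) & _SEED_MASK

    dx_eq = np.zeros(params.n_equilibration_sweeps)
    snap_dummy = np.zeros((0, work.n, 3))
    ion_step, np_step, _, _, _ = _mc_kernel(
        work.positions, work.charges, work.radii, work.cell, modes, lb,
        k_spring, spec.x, params.n_equilibration_sweeps,
        params.ion_max_step, params.np_max_step, params.jump_fraction,
        params.np_attempts_per_sweep,
        jump_bias, bias_r, bias_c0x, bias_c1x, bias_cy, bias_cz,
        True, params.tune_interval,
        dx_eq, 0, snap_dummy, seed_eq,
    )

    n_snap = params.n_production_sweeps // params.snapshot_stride \
        if params.snapshot_stride > 0 else 0
    snaps = np.zeros((n_snap, work.n, 3))
    dx_pr = np.zeros(params.n_production_sweeps)
    ion_step, np_step, rate_ion, rate_np, snap_count = _mc_kernel(
        work.positions, work.charges, work.radii, work.cell, modes, lb,
        k_spring, spec.x, params.n_production_sweeps,
        ion_step, np_step, params.jump_fraction,
        params.np_attempts_per_sweep,
        jump_bias, bias_r, bias_c0x, bias_c1x, bias_cy, bias_cz,
        False, params.tune_interval,
        dx_pr, params.snapshot_stride, snaps, seed_pr,
    )

    warnings = []
    for label, rate in (("ion", rate_ion), ("nanoparticle", rate_np)):
        if not (0.1 <= rate <= 0.9):
            warnings.append(
                f"{label} acceptance rate {rate:.2f} outside [0.1, 0.9] "
                "after tuning"
            )
    return MCRun(
        dx_series=dx_pr,
        snapshots=snaps[:snap_count],
        acceptance_ion=rate_ion,
        acceptance_np=rate_np,
        ion_step=ion_step,
        np_step=np_step,
        warnings=warnings,
        configuration=work,
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _block_stderr(series: np.ndarray, block_count: int) -> float:
    """Standard error of the mean from non-overlapping block averages."""
    n = len(series)
    if block_count < 2 or n < 2 * block_count:
        block_count = max(2, min(block_count, n // 2))
    block = n // block_count
    means = series[: block * block_count].reshape(block_count, block).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(block_count))


def estimate_force(dx_series: np.ndarray, k: float, block_count: int,
                   x: float = float("nan")) -> ForceSample:
    """Mean-force estimate F = k <Δx> (nN) with a block-averaged error bar.

    ``k`` is in nN/Å and ``dx_series`` in Å; correlations in the series are
    absorbed by the block averaging as long as blocks exceed the correlation
    time.
    """
    dx_series = np.asarray(dx_series, dtype=float)
    if dx_series.size == 0:
        raise InvalidParameterError("empty Δx series")
    if dx_series.size < block_count:
        raise InvalidParameterError(
            f"series of length {dx_series.size} too short for "
            f"{block_count} blocks"
        )
    mean_dx = float(dx_series.mean())
    if dx_series.size >= 4 and np.ptp(dx_series) > 0:
        err = k * _block_stderr(dx_series, block_count)
    else:
        err = 0.0
    return ForceSample(
        x=x, mean_dx=mean_dx, F=k * mean_dx, stderr_F=err,
        n_samples=int(dx_series.size),
    )


def integrate_pmf(forces: Sequence[ForceSample], x_ref: float,
                  temperature: float = 298.15) -> PMFCurve:
    """Trapezoidal integration of mean forces from each x up to x_ref.

    ΔG(x) = ∫_x^{x_ref} F dx', converted from nN·Å to kBT; the error is the
    quadrature sum of the trapezoid weights times the per-point force errors;
    ΔG(x_ref) = 0 exactly.
    """
    xs = np.array([f.x for f in forces], dtype=float)
    if np.any(np.diff(xs) <= 0):
        raise InvalidParameterError("force samples must have strictly "
                                    "ascending x")
    if not np.any(np.isclose(xs, x_ref)):
        raise InvalidParameterError("force grid must include x_ref")
    conv = nn_angstrom_to_kbt(temperature)
    fs = np.array([f.F for f in forces])
    es = np.array([f.stderr_F for f in forces])
    n = len(xs)
    dg = np.zeros(n)
    var = np.zeros(n)
    # integrate right-to-left, accumulating trapezoid segments
    for i in range(n - 2, -1, -1):
        h = xs[i + 1] - xs[i]
        dg[i] = dg[i + 1] + 0.5 * h * (fs[i] + fs[i + 1])
        var[i] = var[i + 1] + (0.5 * h * es[i]) ** 2 + (0.5 * h * es[i + 1]) ** 2
    return PMFCurve(
        x_values=xs, dG=dg * conv, dG_err=np.sqrt(var) * conv,
        method="MC", x_ref=x_ref,
    )


def convergence_report(separation_series: np.ndarray,
                       block_count: int = 20) -> dict:
    """Split-half convergence diagnostic on a separation time series.

    Returns the running mean, the two half means with block-averaged errors,
    and ``converged`` = |half difference| < 2 × combined stderr.
    """
    s = np.asarray(separation_series, dtype=float)
    half = len(s) // 2
    a, b = s[:half], s[half:]
    ma, mb = float(a.mean()), float(b.mean())
    ea = _block_stderr(a, block_count) if len(a) >= 4 else 0.0
    eb = _block_stderr(b, block_count) if len(b) >= 4 else 0.0
    combined = math.hypot(ea, eb)
    converged = abs(ma - mb) < 2.0 * combined if combined > 0 else ma == mb
    return {
        "running_mean": np.cumsum(s) / np.arange(1, len(s) + 1),
        "half_means": (ma, mb),
        "half_errors": (ea, eb),
        "converged": bool(converged),
    }


# ---------------------------------------------------------------------------
# reservoir calibration
# ---------------------------------------------------------------------------

def _far_region(spec: SystemSpec, box: np.ndarray, r_cut: float,
                n_lattice: int = 40) -> float:
    """Volume (Å³) of the region accessible to ion *centres* (a hard-wall
    margin of one ion radius per face) farther than r_cut from both
    nanoparticle centres, by lattice quadrature.  Using the centre-accessible
    volume matters: the concentration plateau that corresponds to the
    mean-field bulk is counts per accessible volume, and the wall margin is
    8-15% of the cell at these box sizes."""
    r_i = spec.ion_radius
    axes = [np.linspace(r_i, box[d] - r_i, n_lattice) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)
    center = box / 2.0
    far = np.ones((n_lattice,) * 3, dtype=bool)
    for sgn in (-1.0, 1.0):
        c = center + np.array([sgn * spec.x / 2.0, 0.0, 0.0])
        far &= ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
                > r_cut**2)
    v_acc = float(np.prod(box - 2.0 * r_i))
    return v_acc * far.mean()


def calibrate_reservoir(spec: SystemSpec, params: MCParams, rounds: int = 3,
                        probe_sweeps: int = 20_000) -> int:
    """Extra salt pairs needed so the far-field concentration matches c0.

    In a closed canonical cell the bound ion layers around the two particles
    deplete the bulk; the naive count round(c0·V) then under-screens, which
    biases the mean force attractive.  This probe runs short chains, measures
    the species concentration in the region farther than 2.5 λ_D from both
    ion-exclusion surfaces, and tops the reservoir up until it matches the
    nominal bulk.  Returns the correction (pairs) for this condition; it is
    insensitive to x and can be reused across separation windows.
    """
    box = np.asarray(spec.box, dtype=float)
    r_cut = spec.contact_radius + 2.5 * spec.debye_len
    r_cut = min(r_cut, 0.45 * float(box.min()))
    v_far = _far_region(spec, box, r_cut)
    target = spec.n0 * v_far
    extra = int(math.ceil(spec.Z / spec.z)) if spec.Z > 0 else 0
    center = box / 2.0
    probe = dataclasses.replace(
        params, n_equilibration_sweeps=max(8000, probe_sweeps // 2),
        n_production_sweeps=probe_sweeps, snapshot_stride=50,
    )
    for rnd in range(rounds):
        cfg = build_system(spec, (params.seed * 7919 + rnd) & _SEED_MASK,
                           extra_pairs=extra)
        run = run_chain(cfg, spec, probe)
        snaps = run.snapshots
        ions = snaps[:, 2:, :]
        d0 = np.linalg.norm(ions - (center - [spec.x / 2, 0, 0]), axis=2)
        d1 = np.linalg.norm(ions - (center + [spec.x / 2, 0, 0]), axis=2)
        far = (d0 > r_cut) & (d1 > r_cut)
        qion = cfg.charges[2:]
        n_cat = (far & (qion > 0)[None, :]).sum(axis=1).mean()
        n_ani = (far & (qion < 0)[None, :]).sum(axis=1).mean()
        measured = 0.5 * (n_cat + n_ani)
        v_acc = float(np.prod(box - 2.0 * spec.ion_radius))
        deficit = (target - measured) / v_far * v_acc
        step = int(round(deficit))
        cap = int(math.ceil(2.0 * spec.Z / spec.z)) + 2
        step = max(-cap, min(cap, step))
        if step == 0:
            break
        extra = max(extra + step, 0)
    return extra


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def default_x_grid(x_ref: float = 40.0) -> np.ndarray:
    """The force/integration grid: 22, 24, ..., x_ref Å."""
    return np.arange(22.0, x_ref + 1e-9, 2.0)


def pmf_mc(spec: SystemSpec, params: MCParams,
           x_values: Iterable[float] | None = None,
           keep_runs_at: Iterable[float] = (),
           calibrate: bool = True) -> tuple:
    """Compute the full MC PMF curve for one (Z, z, c0) condition.

    For each separation a fresh box is built (per-x sizing rule), the chain is
    equilibrated and sampled, and the spring forces are integrated from
    x_ref down.  The salt reservoir is calibrated once per condition (at the
    mid-range separation) unless ``calibrate=False``.  Returns
    ``(PMFCurve, [ForceSample], {x: MCRun})`` where runs are retained only
    for separations listed in ``keep_runs_at``.
    """
    xs = np.sort(np.asarray(list(x_values) if x_values is not None
                            else default_x_grid(spec.x_ref), dtype=float))
    keep = {round(float(v), 6) for v in keep_runs_at}
    extra = 0
    if calibrate and spec.Z > 0:
        x_mid = float(xs[len(xs) // 2])
        extra = calibrate_reservoir(spec.at_separation(x_mid), params)
    forces = []
    runs = {}
    for i, x in enumerate(xs):
        spec_x = spec.at_separation(float(x))
        seed_x = (int(params.seed) * 1000003 + 7919 * i) & _SEED_MASK
        cfg = build_system(spec_x, seed_x, extra_pairs=extra)
        p = dataclasses.replace(params, seed=seed_x)
        want_snaps = round(float(x), 6) in keep
        if not want_snaps:
            p = dataclasses.replace(p, snapshot_stride=0)
        run = run_chain(cfg, spec_x, p)
        forces.append(
            estimate_force(run.dx_series, spec.k_spring, params.block_count,
                           x=float(x))
        )
        if want_snaps:
            runs[float(x)] = run
    curve = integrate_pmf(forces, spec.x_ref, spec.temperature)
    return curve, forces, runs
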