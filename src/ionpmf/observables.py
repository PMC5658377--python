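"""Comparison statistics computed identically from MC samples and PB fields.

The central objects are the net ion charge fraction

    Q(r) = -(1/Z) ∫_{<r} Σ_i z_i c_i(r) d³r,

accumulated in the half-space belonging to one nanoparticle (the bisector
plane between the two oppositely charged particles is an equipotential at
zero, so each half is dominated by its own particle), and the relative PMF
deviation between the two routes at the reference separation x0 = 22 Å,

    ΔΔg = |(ΔG_MC(x0) − ΔG_PB(x0)) / ΔG_MC(x0)|.

The apparent coupling parameter |Z|ΔQ* = |Z|·|Q_MC − Q_PB| at r = 14 Å (one
ion diameter off contact, where the profile difference peaks) tracks ΔΔg
across salt conditions and charge densities.  By symmetry the profiles of the
two particles are charge-conjugates; both are computed and averaged.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .model_core import Configuration, InvalidParameterError, SystemSpec
from .mc_engine import MCRun, _block_stderr
from .pb_solver import PBLevel

__all__ = [
    "IonChargeProfile",
    "ComparisonReport",
    "net_charge_fraction_mc",
    "net_charge_fraction_pb",
    "delta_delta_g",
    "apparent_parameter",
    "compare",
    "equivalent_salt",
    "charge_density_landscape_mc",
    "charge_density_landscape_pb",
    "write_landscape_csv",
    "default_r_bins",
]


@dataclasses.dataclass
class IonChargeProfile:
    """Cumulative net bound-ion charge fraction Q(r) around a nanoparticle,
    averaged over the two (charge-conjugate) half-spaces."""

    r_bins: np.ndarray  # Å, ascending bin edges at which Q is evaluated
    Q: np.ndarray
    Q_err: np.ndarray
    x: float  # nanoparticle separation, Å
    method: str  # {"MC", "PB"}
    asymmetry: float = 0.0  # max |Q_+ − Q_−| over bins, symmetry check

    def at(self, r: float) -> float:
        idx = np.nonzero(np.isclose(self.r_bins, r))[0]
        if idx.size == 0:
            raise InvalidParameterError(f"profile has no bin at r = {r} Å")
        return float(self.Q[idx[0]])


@dataclasses.dataclass
class ComparisonReport:
    """Headline MC-vs-PB deviation statistics at one state point."""

    ddg: float  # ΔΔg, dimensionless
    dQ_star: float  # |Q_MC − Q_PB| at r = 14 Å
    apparent: float  # |Z|·ΔQ*
    x0: float = 22.0
    dG_mc: float = float("nan")
    dG_pb: float = float("nan")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_r_bins(r_max: float = 30.0, width: float = 0.5) -> np.ndarray:
    """Radial evaluation points 0.5, 1.0, ..., r_max Å (0.5 Å bins)."""
    return np.arange(width, r_max + 1e-9, width)


def net_charge_fraction_mc(run: MCRun, spec: SystemSpec,
                           r_bins: np.ndarray | None = None,
                           block_count: int = 20) -> IonChargeProfile:
    """Q(r) from MC snapshots.

    For each snapshot and each nanoparticle, ions are assigned to the
    particle's side of the instantaneous bisector plane (normal to x); the
    net ion charge within r of the particle centre is normalised by −1/Z_p
    with Z_p the particle's signed charge.  The two per-particle profiles are
    averaged; their maximum difference is reported as the symmetry check.
    """
    snaps = run.snapshots
    if snaps.shape[0] == 0:
        raise InvalidParameterError("run holds no snapshots")
    if r_bins is None:
        r_bins = default_r_bins()
    cfg = run.configuration
    qion = cfg.charges[2:]
    n_s = snaps.shape[0]
    prof_p = np.zeros((n_s, len(r_bins)))
    prof_m = np.zeros((n_s, len(r_bins)))
    for s_idx in range(n_s):
        s = snaps[s_idx]
        x_mid = 0.5 * (s[0, 0] + s[1, 0])
        ions = s[2:]
        for p_idx, prof in ((0, prof_p), (1, prof_m)):
            d = np.linalg.norm(ions - s[p_idx], axis=1)
            # ties on the plane resolved by side of the first particle
            side = ions[:, 0] < x_mid if p_idx == 0 else ions[:, 0] >= x_mid
            order = np.argsort(d)
            d_sorted = d[order]
            q_sorted = np.where(side, qion, 0.0)[order]
            cum = np.cumsum(q_sorted)
            k = np.searchsorted(d_sorted, r_bins, side="right")
            net = np.where(k > 0, cum[np.maximum(k - 1, 0)], 0.0)
            prof[s_idx] = -net / cfg.charges[p_idx]
    mean_p = prof_p.mean(axis=0)
    mean_m = prof_m.mean(axis=0)
    q_mean = 0.5 * (mean_p + mean_m)
    both = 0.5 * (prof_p + prof_m)
    err = np.array([_block_stderr(both[:, j], block_count)
                    if n_s >= 4 else 0.0 for j in range(len(r_bins))])
    return IonChargeProfile(
        r_bins=np.asarray(r_bins, dtype=float), Q=q_mean, Q_err=err,
        x=spec.x, method="MC",
        asymmetry=float(np.max(np.abs(mean_p - mean_m))),
    )


def net_charge_fraction_pb(levels: Sequence[PBLevel], spec: SystemSpec,
                           r_bins: np.ndarray | None = None
                           ) -> IonChargeProfile:
    """Q(r) from the converged PB field: half-space integral of the Boltzmann
    net ion charge density −2 z n0 sinh(z u) on the finest grid."""
    if r_bins is None:
        r_bins = default_r_bins()
    grid = levels[-1].grid
    u = grid.psi
    rho = -2.0 * spec.z * spec.n0 * np.sinh(np.clip(spec.z * u, -60.0, 60.0))
    rho = np.where(grid.accessibility.astype(bool), rho, 0.0)
    xs, ys, zs = grid.axes()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    h3 = grid.h**3
    centers = np.array([[-spec.x / 2.0, 0.0, 0.0], [spec.x / 2.0, 0.0, 0.0]])
    zps = np.array([spec.Z, -spec.Z])
    profs = []
    for c, zp, side in (
        (centers[0], zps[0], X < 0.0),
        (centers[1], zps[1], X >= 0.0),
    ):
        d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        dd = d[side].ravel()
        rr = rho[side].ravel()
        order = np.argsort(dd)
        cum = np.cumsum(rr[order]) * h3
        k = np.searchsorted(dd[order], r_bins, side="right")
        net = np.where(k > 0, cum[np.maximum(k - 1, 0)], 0.0)
        profs.append(-net / zp)
    q_mean = 0.5 * (profs[0] + profs[1])
    return IonChargeProfile(
        r_bins=np.asarray(r_bins, dtype=float), Q=q_mean,
        Q_err=np.zeros_like(q_mean), x=spec.x, method="PB",
        asymmetry=float(np.max(np.abs(profs[0] - profs[1]))),
    )


def delta_delta_g(dg_mc: float, dg_pb: float) -> float:
    """ΔΔg = |(ΔG_MC − ΔG_PB)/ΔG_MC| at the comparison separation."""
    if dg_mc == 0:
        raise InvalidParameterError("ΔΔg undefined for ΔG_MC = 0")
    return abs((dg_mc - dg_pb) / dg_mc)


def apparent_parameter(profile_mc: IonChargeProfile,
                       profile_pb: IonChargeProfile, Z: float,
                       r_star: float = 14.0) -> float:
    """|Z|ΔQ* = |Z| · |Q_MC(r*) − Q_PB(r*)| with r* = 14 Å."""
    return abs(Z) * abs(profile_mc.at(r_star) - profile_pb.at(r_star))


def compare(dg_mc: float, dg_pb: float, profile_mc: IonChargeProfile,
            profile_pb: IonChargeProfile, Z: float,
            x0: float = 22.0) -> ComparisonReport:
    dq = abs(profile_mc.at(14.0) - profile_pb.at(14.0))
    return ComparisonReport(
        ddg=delta_delta_g(dg_mc, dg_pb), dQ_star=dq, apparent=abs(Z) * dq,
        x0=x0, dG_mc=dg_mc, dG_pb=dg_pb,
    )


def equivalent_salt(c0_11: Sequence[float], value_11: Sequence[float],
                    target: float) -> float:
    """The 1:1 concentration whose observable (ΔG(22 Å) or Q(22 Å)) matches a
    2:2 target, by piecewise-linear interpolation in (log10 c0, value).

    Refuses to extrapolate outside the tabulated 1:1 ladder.
    """
    c = np.asarray(c0_11, dtype=float)
    v = np.asarray(value_11, dtype=float)
    if len(c) != len(v) or len(c) < 2:
        raise InvalidParameterError("need at least two ladder points")
    order = np.argsort(c)
    c, v = c[order], v[order]
    lo, hi = min(v[0], v[-1]), max(v[0], v[-1])
    if not (lo <= target <= hi):
        raise InvalidParameterError(
            f"target {target} outside ladder range [{lo}, {hi}]; "
            "extrapolation refused"
        )
    if not (np.all(np.diff(v) > 0) or np.all(np.diff(v) < 0)):
        raise InvalidParameterError("ladder observable must be monotone in c0")
    logc = np.log10(c)
    if v[0] < v[-1]:
        return float(10.0 ** np.interp(target, v, logc))
    return float(10.0 ** np.interp(target, v[::-1], logc[::-1]))


# ---------------------------------------------------------------------------
# 2D net-charge landscapes
# ---------------------------------------------------------------------------

def _cyl_bins(spec: SystemSpec, plane_resolution: float):
    half_ax = spec.x / 2.0 + 2.5 * spec.contact_radius
    rad_max = 2.5 * spec.contact_radius
    ax_edges = np.arange(-half_ax, half_ax + plane_resolution,
                         plane_resolution)
    rad_edges = np.arange(0.0, rad_max + plane_resolution, plane_resolution)
    return ax_edges, rad_edges


def charge_density_landscape_mc(run: MCRun, spec: SystemSpec,
                                plane_resolution: float = 1.0) -> dict:
    """Net ion charge density (e/Å³) on the plane through both centres,
    cylindrically averaged about the inter-particle axis.

    Returns axial/radial bin edges and the density map (axial × radial).
    """
    snaps = run.snapshots
    if snaps.shape[0] == 0:
        raise InvalidParameterError("run holds no snapshots")
    cfg = run.configuration
    qion = cfg.charges[2:]
    ax_edges, rad_edges = _cyl_bins(spec, plane_resolution)
    hist = np.zeros((len(ax_edges) - 1, len(rad_edges) - 1))
    mid = cfg.cell / 2.0
    for s in snaps:
        ions = s[2:] - mid
        a = ions[:, 0]
        rad = np.sqrt(ions[:, 1] ** 2 + ions[:, 2] ** 2)
        h, _, _ = np.histogram2d(a, rad, bins=[ax_edges, rad_edges],
                                 weights=qion)
        hist += h
    # cylindrical shell volumes per (axial, radial) bin
    da = np.diff(ax_edges)
    shell = np.pi * (rad_edges[1:] ** 2 - rad_edges[:-1] ** 2)
    vol = da[:, None] * shell[None, :]
    density = hist / (snaps.shape[0] * vol)
    return {"axial_edges": ax_edges, "radial_edges": rad_edges,
            "density": density, "method": "MC"}


def write_landscape_csv(landscape: dict, path, **meta) -> None:
    """Long-format CSV of a 2D net-charge landscape: one row per
    (axial, radial) bin centre with the density in e/Å³."""
    import pandas as pd

    a = landscape["axial_edges"]
    r = landscape["radial_edges"]
    ac = 0.5 * (a[:-1] + a[1:])
    rc = 0.5 * (r[:-1] + r[1:])
    A, R = np.meshgrid(ac, rc, indexing="ij")
    df = pd.DataFrame({
        "axial_A": A.ravel(), "radial_A": R.ravel(),
        "density_e_per_A3": landscape["density"].ravel(),
        "method": landscape["method"],
    })
    for k, v in meta.items():
        df[k] = v
    df.to_csv(path, index=False)


def charge_density_landscape_pb(levels: Sequence[PBLevel], spec: SystemSpec,
                                plane_resolution: float = 1.0) -> dict:
    """PB net ion charge density on the same cylindrical raster as the MC
    landscape (cylindrically binned from the finest grid)."""
    grid = levels[-1].grid
    u = grid.psi
    rho = -2.0 * spec.z * spec.n0 * np.sinh(np.clip(spec.z * u, -60.0, 60.0))
    rho = np.where(grid.accessibility.astype(bool), rho, 0.0)
    xs, ys, zs = grid.axes()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    a = X.ravel()
    rad = np.sqrt(Y**2 + Z**2).ravel()
    ax_edges, rad_edges = _cyl_bins(spec, plane_resolution)
    w, _, _ = np.histogram2d(a, rad, bins=[ax_edges, rad_edges],
                             weights=rho.ravel())
    n, _, _ = np.histogram2d(a, rad, bins=[ax_edges, rad_edges])
    with np.errstate(invalid="ignore"):
        density = np.where(n > 0, w / np.maximum(n, 1), 0.0)
    return {"axial_edges": ax_edges, "radial_edges": rad_edges,
            "density": density, "method": "PB"}
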