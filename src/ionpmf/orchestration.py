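"""Sweep orchestration: configuration files, reproducible seeding, result
serialization and resumable (Z, z, c0, x) comparison runs, plus miniature
fixture systems with analytically known behaviour.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import observables as obs
from .mc_engine import MCParams, PMFCurve, pmf_mc
from .model_core import (
    Configuration,
    InvalidParameterError,
    SystemSpec,
    build_system,
    spring_constant_kbt,
)
from .pb_solver import focusing_solve, pb_pmf, reduced_schedule

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "run_comparison",
    "make_fixture",
    "combination_seed",
    "write_pmf_csv",
]

_SEED_MASK = 0x7FFFFFFF

_PHYSICAL_KEYS = {"epsilon", "temperature", "k_spring", "x_ref"}
_MC_KEYS = {f.name for f in dataclasses.fields(MCParams)} - {"seed"}


@dataclasses.dataclass
class RunConfig:
    """A sweep definition: lists of Z, z, c0 (and the comparison separation
    x0), shared physical defaults, MC parameters and PB schedule knobs."""

    Z: list
    z: list
    c0: list
    x0: float = 22.0
    x_grid: list | None = None  # force/integration grid; default 22..40 by 2
    physical: dict = dataclasses.field(default_factory=dict)
    mc: dict = dataclasses.field(default_factory=dict)
    pb_final_h: float = 0.5
    output_dir: str = "ionpmf_out"
    seed_base: int = 1

    def __post_init__(self) -> None:
        for key in self.physical:
            if key not in _PHYSICAL_KEYS:
                raise InvalidParameterError(f"unknown physical key {key!r}")
        for key in self.mc:
            if key not in _MC_KEYS:
                raise InvalidParameterError(f"unknown mc key {key!r}")
        if not self.Z or not self.z or not self.c0:
            raise InvalidParameterError("sweep lists Z, z, c0 must be "
                                        "non-empty")
        # every sweep combination must produce a valid SystemSpec
        for Z, z, c0 in self.combinations():
            SystemSpec(Z=Z, z=z, c0=c0, x=self.x0, **self.physical)

    def combinations(self):
        for Z in self.Z:
            for z in self.z:
                for c0 in self.c0:
                    yield float(Z), int(z), float(c0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def combination_seed(seed_base: int, Z: float, z: int, c0: float) -> int:
    """Stable per-combination seed: seed_base offset by a CRC of the
    combination label (kept below 2^31)."""
    label = f"Z={Z:g};z={z};c0={c0:g}".encode()
    return (int(seed_base) + zlib.crc32(label)) & _SEED_MASK


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are named in
    the error."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise InvalidParameterError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            raise InvalidParameterError(f"unknown config key {key!r}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def write_pmf_csv(curve: PMFCurve, forces, spec: SystemSpec, seed: int,
                  path) -> None:
    """Long-format PMF table: x, force, PMF, condition metadata."""
    fmap = {f.x: f for f in forces} if forces else {}
    rows = []
    for x, dg, de in zip(curve.x_values, curve.dG, curve.dG_err):
        f = fmap.get(float(x))
        rows.append({
            "x_A": float(x),
            "F_nN": f.F if f else math.nan,
            "F_err": f.stderr_F if f else math.nan,
            "dG_kT": float(dg),
            "dG_err": float(de),
            "method": curve.method,
            "Z": spec.Z, "z": spec.z, "c0_M": spec.c0, "seed": seed,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_comparison(cfg: RunConfig, progress=None) -> dict:
    """Run the full MC + PB comparison for every sweep combination.

    Per combination: MC PMF over the x grid (snapshots kept at x0), PB PMF at
    the same x values, Q(r) profiles both ways at x0, and a deviation report.
    Artifacts land in ``cfg.output_dir`` with a manifest; combinations whose
    outputs already match the manifest are skipped, and individual failures
    are recorded without aborting the sweep.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) \
        if manifest_path.exists() else {"entries": {}}
    results = {}
    for Z, z, c0 in cfg.combinations():
        key = f"Z{Z:g}_z{z}_c{c0:g}"
        entry = manifest["entries"].get(key)
        if entry is not None and all(
            (out_dir / f).exists() and _sha256(out_dir / f) == h
            for f, h in entry["files"].items()
        ):
            results[key] = {"status": "cached", **entry["report"]}
            continue
        if progress:
            progress(key)
        try:
            results[key] = _run_point(cfg, Z, z, c0, out_dir, key, manifest)
        except Exception as exc:  # individual point failure: record, continue
            results[key] = {"status": "failed", "error": str(exc)}
            manifest["entries"].pop(key, None)
        manifest_path.write_text(json.dumps(manifest, indent=1))
    return results


def _run_point(cfg: RunConfig, Z: float, z: int, c0: float, out_dir: Path,
               key: str, manifest: dict) -> dict:
    seed = combination_seed(cfg.seed_base, Z, z, c0)
    spec = SystemSpec(Z=Z, z=z, c0=c0, x=cfg.x0, **cfg.physical)
    params = MCParams(seed=seed, **cfg.mc)
    xs = cfg.x_grid if cfg.x_grid is not None else None
    curve_mc, forces, runs = pmf_mc(spec, params, x_values=xs,
                                    keep_runs_at=[cfg.x0])
    sched = reduced_schedule(spec, final_h=cfg.pb_final_h)
    curve_pb, _ = pb_pmf(spec, sched, x_values=[cfg.x0, spec.x_ref])
    levels = focusing_solve(spec, sched)
    prof_mc = obs.net_charge_fraction_mc(runs[cfg.x0], spec)
    prof_pb = obs.net_charge_fraction_pb(levels, spec)
    report = obs.compare(curve_mc.interp(cfg.x0), curve_pb.interp(cfg.x0),
                         prof_mc, prof_pb, Z, x0=cfg.x0)

    files = {}
    mc_csv = f"{key}_pmf_mc.csv"
    pb_csv = f"{key}_pmf_pb.csv"
    q_csv = f"{key}_q_profiles.csv"
    rep_json = f"{key}_report.json"
    write_pmf_csv(curve_mc, forces, spec, seed, out_dir / mc_csv)
    write_pmf_csv(curve_pb, None, spec, seed, out_dir / pb_csv)
    qf = pd.concat([
        pd.DataFrame({"r_A": p.r_bins, "Q": p.Q, "Q_err": p.Q_err,
                      "method": p.method, "Z": Z, "z": z, "c0_M": c0,
                      "x_A": cfg.x0})
        for p in (prof_mc, prof_pb)
    ])
    qf.to_csv(out_dir / q_csv, index=False)
    run22 = runs[cfg.x0]
    payload = {"report": report.to_dict(), "seed": seed,
               "params": dataclasses.asdict(params),
               "pb_final_h": cfg.pb_final_h,
               "mc_acceptance": {"ion": run22.acceptance_ion,
                                 "nanoparticle": run22.acceptance_np},
               "mc_warnings": run22.warnings,
               "pb_iterations": levels[-1].iterations,
               "pb_residual": levels[-1].residual}
    (out_dir / rep_json).write_text(json.dumps(payload, indent=1))
    for name in (mc_csv, pb_csv, q_csv, rep_json):
        files[name] = _sha256(out_dir / name)
    manifest["entries"][key] = {"files": files, "report": report.to_dict()}
    return {"status": "computed", **report.to_dict()}


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("ideal_gas", "one_ion", "dh_sphere", "spring_only",
                 "tiny_pair")


def make_fixture(name: str, seed: int = 7) -> dict:
    """Deterministic miniature systems with oracle-computed expectations.

    ideal_gas   : 24 uncharged "ions" in a 40 Å cube — uniform density.
    one_ion     : one fixed charged nanoparticle + one counterion in a small
                  box — radial density follows the 1-particle Boltzmann
                  factor (numerical quadrature oracle attached).
    dh_sphere   : a |Z|=1 sphere in 10 mM 1:1 salt with the analytic
                  linearized ψ(r) table.
    spring_only : two neutral nanoparticles joined by the 9 nN/Å spring —
                  Δx is Gaussian with std sqrt(kBT/k) ≈ 0.068 Å.
    tiny_pair   : ±6e nanoparticles with two salt pairs — the smallest
                  charged system exercising every energy path.
    """
    if name not in FIXTURE_NAMES:
        raise InvalidParameterError(f"unknown fixture {name!r}; "
                                    f"choose from {FIXTURE_NAMES}")
    if name == "ideal_gas":
        rng = np.random.default_rng(seed)
        n = 24
        cell = np.full(3, 40.0)
        pos = rng.uniform(2.0, 38.0, size=(n, 3))
        cfg = Configuration(pos, np.zeros(n), np.full(n, 2.0),
                            ["cation"] * n, cell)
        return {"config": cfg, "expected": {"uniform_density": n / 40.0**3}}
    if name == "spring_only":
        cell = np.full(3, 80.0)
        pos = np.array([[29.0, 40.0, 40.0], [51.0, 40.0, 40.0]])
        cfg = Configuration(pos, np.zeros(2), np.full(2, 10.0),
                            ["nanoparticle"] * 2, cell)
        std = 1.0 / math.sqrt(spring_constant_kbt(9.0))
        return {"config": cfg, "x_rest": 22.0,
                "expected": {"dx_std": std}}  # ≈ 0.0676 Å
    if name == "one_ion":
        cell = np.full(3, 44.0)
        pos = np.array([[22.0, 22.0, 22.0], [36.0, 22.0, 22.0]])
        cfg = Configuration(pos, np.array([2.0, -2.0]),
                            np.array([10.0, 2.0]),
                            ["nanoparticle", "anion"], cell)

        def boltzmann_radial(r_edges, lb):
            """Deterministic quadrature of the 1-ion Boltzmann factor over
            the accessible box volume, binned by distance from the centre."""
            g = np.linspace(2.0, 42.0, 161)
            X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
            r = np.sqrt((X - 22.0) ** 2 + (Y - 22.0) ** 2 + (Z - 22.0) ** 2)
            w = np.zeros_like(r)
            ok = r >= 12.0
            w[ok] = np.exp(4.0 * lb / r[ok])  # U = -4 lB/r for the +2/-2 pair
            p, _ = np.histogram(r.ravel(), bins=r_edges, weights=w.ravel())
            return p / p.sum()

        return {"config": cfg, "oracle": boltzmann_radial}
    if name == "dh_sphere":
        spec = SystemSpec(Z=1, z=1, c0=0.01, x=30.0)
        from .pb_solver import dh_potential

        r = np.arange(14.0, 31.0, 2.0)
        table = dh_potential(
            np.column_stack([r, np.zeros_like(r), np.zeros_like(r)]),
            np.zeros((1, 3)), np.array([1.0]),
            spec.bjerrum, spec.kappa, spec.contact_radius,
        )
        return {"spec": spec, "r": r, "expected_psi": table}
    # tiny_pair
    cell = np.full(3, 60.0)
    pos = np.array([
        [19.0, 30.0, 30.0], [41.0, 30.0, 30.0],
        [30.0, 44.0, 30.0], [30.0, 16.0, 30.0],
        [30.0, 30.0, 44.0], [30.0, 30.0, 16.0],
    ])
    cfg = Configuration(
        pos, np.array([6.0, -6.0, 1.0, 1.0, -1.0, -1.0]),
        np.array([10.0, 10.0, 2.0, 2.0, 2.0, 2.0]),
        ["nanoparticle", "nanoparticle", "cation", "cation",
         "anion", "anion"], cell,
    )
    return {"config": cfg}
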