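"""Primitive-model definitions shared by the Monte Carlo and Poisson-Boltzmann
routes.

The physical system is two oppositely charged nanospheres (radius 10 Å,
charges +Z e and -Z e) immersed in a symmetric z:-z electrolyte whose ions are
charged hard spheres of radius 2 Å, all in a uniform dielectric continuum
(ε = 78 water).  Interactions are Coulomb plus hard-core exclusion.

Internal unit system
--------------------
* length   : Å
* charge   : elementary charge e
* energy   : kBT  (T fixed per :class:`SystemSpec`, default 298.15 K)
* concentration : mol/L at the API boundary, number density per Å³ internally

The single bridge between SI constants and this unit system is
:func:`bjerrum_length` (plus the nN·Å → kBT conversion used by the spring
force estimator).  Keeping exactly one conversion point removes a whole class
of unit bugs from both simulation routes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import numpy as np

__all__ = [
    "ELEMENTARY_CHARGE",
    "BOLTZMANN",
    "VACUUM_PERMITTIVITY",
    "AVOGADRO",
    "MOLAR_TO_PER_A3",
    "NANOPARTICLE_RADIUS",
    "ION_RADIUS",
    "OVERLAP",
    "bjerrum_length",
    "debye_length",
    "inverse_debye_length",
    "thermal_energy_joules",
    "spring_constant_kbt",
    "nn_angstrom_to_kbt",
    "ChargedSphere",
    "SystemSpec",
    "Configuration",
    "pair_energy",
    "total_energy",
    "build_system",
]

# CODATA 2018 exact / recommended values
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
AVOGADRO = 6.02214076e23  # 1/mol

#: mol/L -> number density in Å^-3
MOLAR_TO_PER_A3 = AVOGADRO / 1.0e27

NANOPARTICLE_RADIUS = 10.0  # Å
ION_RADIUS = 2.0  # Å

#: sentinel returned by energy routines when two hard cores interpenetrate
OVERLAP = math.inf


class InvalidParameterError(ValueError):
    """A physical or numerical parameter is outside its allowed domain."""


class PlacementError(RuntimeError):
    """Random insertion of ions failed: the packing is too dense for the box."""


def thermal_energy_joules(temperature: float = 298.15) -> float:
    """kBT in joules."""
    if temperature <= 0:
        raise InvalidParameterError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN * temperature


def bjerrum_length(epsilon: float = 78.0, temperature: float = 298.15) -> float:
    """Bjerrum length lB = e²/(4π ε0 ε kB T) in Å.

    The separation at which two unit charges in the dielectric interact with
    exactly kBT; ≈ 7.19 Å for ε = 78 water at 298.15 K.
    """
    if epsilon <= 0:
        raise InvalidParameterError(f"epsilon must be positive, got {epsilon}")
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0
        * math.pi
        * VACUUM_PERMITTIVITY
        * epsilon
        * thermal_energy_joules(temperature)
    )
    return lb_m * 1.0e10


def inverse_debye_length(
    z: int, c0: float, epsilon: float = 78.0, temperature: float = 298.15
) -> float:
    """Inverse Debye screening length κ in Å⁻¹ for a symmetric z:-z salt.

    κ² = 4π lB Σ_i n_i z_i² = 8π lB z² n0 with n0 the bulk number density of
    each ion species in Å⁻³.
    """
    if c0 <= 0:
        raise InvalidParameterError(f"c0 must be positive, got {c0}")
    n0 = c0 * MOLAR_TO_PER_A3
    lb = bjerrum_length(epsilon, temperature)
    return math.sqrt(8.0 * math.pi * lb * z * z * n0)


def debye_length(
    z: int, c0: float, epsilon: float = 78.0, temperature: float = 298.15
) -> float:
    """Debye screening length λ_D = 1/κ in Å."""
    return 1.0 / inverse_debye_length(z, c0, epsilon, temperature)


def spring_constant_kbt(k_nn_per_a: float, temperature: float = 298.15) -> float:
    """Convert a spring constant from nN/Å to kBT/Å²  (9 nN/Å ≈ 218.6 kBT/Å²)."""
    # 1 nN/Å = 1e-9 N / 1e-10 m = 10 N/m; energy per Å² = k[N/m] * (1e-10 m)²
    return k_nn_per_a * 1.0e-9 * 1.0e-10 / thermal_energy_joules(temperature)


def nn_angstrom_to_kbt(temperature: float = 298.15) -> float:
    """Conversion factor for force×distance: 1 nN·Å = 1e-19 J ≈ 24.3 kBT."""
    return 1.0e-19 / thermal_energy_joules(temperature)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_KINDS = ("nanoparticle", "cation", "anion")


@dataclasses.dataclass
class ChargedSphere:
    """A charged hard sphere: either a nanoparticle or a salt ion.

    Attributes
    ----------
    center : (3,) array, Å
    radius : float, Å
    charge : float, units of e (signed)
    kind : {"nanoparticle", "cation", "anion"}
    """

    center: np.ndarray
    radius: float
    charge: float
    kind: str = "nanoparticle"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise InvalidParameterError("center must be a 3-vector")
        if self.radius <= 0:
            raise InvalidParameterError(f"radius must be positive, got {self.radius}")
        if self.kind not in _KINDS:
            raise InvalidParameterError(f"unknown kind {self.kind!r}")


@dataclasses.dataclass
class SystemSpec:
    """Full physical definition of one (Z, z, c0, x) state point.

    Parameters
    ----------
    Z : float
        Nanoparticle charge magnitude in e; the pair carries +Z and -Z.
    z : int
        Salt valence (1 or 2 for the symmetric 1:1 / 2:2 salts studied).
    c0 : float
        Bulk salt concentration, mol/L.
    x : float
        Centre-to-centre separation of the nanoparticles, Å.
    box : (3,) sequence of side lengths in Å, or None to apply the sizing
        rule: every side at least x + 6 λ_D (cube by default, with a small
        floor so both particles plus an ion layer always fit).
    k_spring : float
        Pseudo-spring stiffness tethering the two nanoparticles, nN/Å.
    x_ref : float
        Outer reference separation at which the PMF is anchored to zero, Å.
    """

    Z: float
    z: int
    c0: float
    x: float
    epsilon: float = 78.0
    temperature: float = 298.15
    box: Sequence[float] | None = None
    k_spring: float = 9.0
    x_ref: float = 40.0
    np_radius: float = NANOPARTICLE_RADIUS
    ion_radius: float = ION_RADIUS
    #: disable the box-sizing rule (miniature fixture systems only)
    validate_box: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise InvalidParameterError("epsilon must be positive")
        if self.c0 <= 0:
            raise InvalidParameterError("c0 must be positive")
        if self.z not in (1, 2):
            raise InvalidParameterError(f"salt valence must be 1 or 2, got {self.z}")
        if not (22.0 <= self.x <= self.x_ref):
            raise InvalidParameterError(
                f"separation x={self.x} must lie in [22, x_ref={self.x_ref}] Å"
            )
        if self.box is None:
            # six Debye lengths of clearance beyond the particle surfaces
            side = self.x + 2.0 * self.np_radius \
                + max(6.0 * self.debye_len, 8.0)
            # reservoir floor: the nominal salt content must at least match
            # the binding demand of one particle (Z/z counterions); the
            # remaining depletion is corrected by reservoir calibration
            min_pairs = self.Z / self.z
            if min_pairs >= 1.0:
                side = max(side, (min_pairs / self.n0) ** (1.0 / 3.0))
            self.box = np.full(3, side)
        else:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise InvalidParameterError("box must have 3 side lengths")
            min_side = self.x + 6.0 * self.debye_len
            if self.validate_box and np.any(self.box < min_side - 1e-9):
                raise InvalidParameterError(
                    f"box sides {self.box} violate the sizing rule: every side "
                    f"must be ≥ x + 6 λ_D = {min_side:.1f} Å"
                )

    # -- derived quantities --------------------------------------------------
    @property
    def bjerrum(self) -> float:
        """Bjerrum length, Å."""
        return bjerrum_length(self.epsilon, self.temperature)

    @property
    def kappa(self) -> float:
        """Inverse Debye length, Å⁻¹."""
        return inverse_debye_length(self.z, self.c0, self.epsilon, self.temperature)

    @property
    def debye_len(self) -> float:
        """Debye length, Å."""
        return 1.0 / self.kappa

    @property
    def n0(self) -> float:
        """Bulk number density of each ion species, Å⁻³."""
        return self.c0 * MOLAR_TO_PER_A3

    @property
    def k_spring_kbt(self) -> float:
        """Spring constant in kBT/Å²."""
        return spring_constant_kbt(self.k_spring, self.temperature)

    @property
    def contact_radius(self) -> float:
        """Distance of closest approach of an ion centre to a nanoparticle
        centre (= nanoparticle radius + ion radius), Å."""
        return self.np_radius + self.ion_radius

    def n_ion_pairs(self) -> int:
        """Number of neutral salt pairs: round(n0 × accessible volume).

        The accessible volume is the box volume minus the two ion-exclusion
        spheres of radius (a + r_ion) around the nanoparticle centres.  Ion
        depletion by binding is not corrected; with boxes ≥ 6 λ_D the error
        is small.
        """
        v_excl = 2.0 * (4.0 / 3.0) * math.pi * self.contact_radius**3
        v_acc = float(np.prod(self.box)) - v_excl
        return int(round(self.n0 * v_acc))

    def at_separation(self, x: float) -> "SystemSpec":
        """A copy of this spec at a different separation (box re-derived when
        it was auto-sized)."""
        return dataclasses.replace(self, x=x, box=None)


@dataclasses.dataclass
class Configuration:
    """A microstate: sphere positions/charges/radii plus the closed cell.

    Spheres are ordered: the two nanoparticles first (index 0 frozen at
    -x/2 from the cell centre with charge +Z, index 1 mobile at +x/2 with
    charge -Z), then all cations, then all anions.  The cell is a closed
    (hard-wall, non-periodic) rectangular box spanning [0, L] per axis.
    """

    positions: np.ndarray  # (N, 3) Å
    charges: np.ndarray  # (N,) e
    radii: np.ndarray  # (N,) Å
    kinds: list
    cell: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.charges = np.ascontiguousarray(self.charges, dtype=float)
        self.radii = np.ascontiguousarray(self.radii, dtype=float)
        self.cell = np.asarray(self.cell, dtype=float)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def spheres(self) -> list:
        return [
            ChargedSphere(self.positions[i].copy(), float(self.radii[i]),
                          float(self.charges[i]), self.kinds[i])
            for i in range(self.n)
        ]

    def net_charge(self) -> float:
        return float(self.charges.sum())

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(), self.charges.copy(), self.radii.copy(),
            list(self.kinds), self.cell.copy(),
        )

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "positions": self.positions.tolist(),
                "charges": self.charges.tolist(),
                "radii": self.radii.tolist(),
                "kinds": list(self.kinds),
                "cell": self.cell.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Configuration":
        d = json.loads(text)
        return cls(
            np.array(d["positions"]), np.array(d["charges"]),
            np.array(d["radii"]), list(d["kinds"]), np.array(d["cell"]),
        )

    def to_xyz(self) -> str:
        """XYZ snapshot; the element column encodes the sphere kind
        (P = nanoparticle, C = cation, A = anion)."""
        sym = {"nanoparticle": "P", "cation": "C", "anion": "A"}
        lines = [str(self.n), "ionpmf configuration cell=" + " ".join(
            f"{s:.3f}" for s in self.cell)]
        for i in range(self.n):
            x, y, zc = self.positions[i]
            lines.append(f"{sym[self.kinds[i]]} {x:.6f} {y:.6f} {zc:.6f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def pair_energy(a: ChargedSphere, b: ChargedSphere, lb: float) -> float:
    """Coulomb + hard-core pair energy in kBT.

    U = q_a q_b lB / r for r ≥ σ_a + σ_b, and the overlap sentinel (+inf)
    for interpenetrating cores — including coincident centres.
    """
    if lb <= 0:
        raise InvalidParameterError("Bjerrum length must be positive")
    r = float(np.linalg.norm(a.center - b.center))
    if r < a.radius + b.radius:
        return OVERLAP
    return a.charge * b.charge * lb / r


def total_energy(cfg: Configuration, lb: float) -> float:
    """Sum of pair energies over all unordered pairs, kBT (overlap → +inf)."""
    pos = cfg.positions
    n = cfg.n
    if n < 2:
        return 0.0
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    rij = r[iu]
    sig = cfg.radii[:, None] + cfg.radii[None, :]
    if np.any(rij < sig[iu]):
        return OVERLAP
    qq = (cfg.charges[:, None] * cfg.charges[None, :])[iu]
    return float(np.sum(qq * lb / rij))


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------

def build_system(spec: SystemSpec, seed: int, max_tries_per_ion: int = 20000,
                 extra_pairs: int = 0) -> Configuration:
    """Build the initial microstate for a state point.

    The +Z nanoparticle sits at cell centre − (x/2, 0, 0) and the −Z one at
    cell centre + (x/2, 0, 0).  ``n_ion_pairs() + extra_pairs`` neutral
    cation/anion pairs are inserted uniformly at random without overlap, with
    every sphere fully inside the closed cell.  Deterministic under a fixed
    seed.  ``extra_pairs`` is the reservoir-calibration correction (see
    :func:`ionpmf.mc_engine.calibrate_reservoir`): the closed canonical cell
    loses bulk ions to the bound layers, and the correction restores the
    nominal far-field concentration.
    """
    box = np.asarray(spec.box, dtype=float)
    center = box / 2.0
    half_x = spec.x / 2.0
    if spec.x + 2.0 * spec.np_radius > box[0]:
        raise InvalidParameterError("box too small to contain both nanoparticles")
    if 2.0 * spec.np_radius > min(box[1], box[2]):
        raise InvalidParameterError("box too small for the nanoparticle radius")

    n_pairs = spec.n_ion_pairs() + int(extra_pairs)
    if n_pairs < 0:
        raise InvalidParameterError("negative ion pair count")
    n = 2 + 2 * n_pairs
    pos = np.empty((n, 3))
    charges = np.empty(n)
    radii = np.empty(n)
    kinds = ["nanoparticle", "nanoparticle"]
    pos[0] = center - np.array([half_x, 0.0, 0.0])
    pos[1] = center + np.array([half_x, 0.0, 0.0])
    charges[0], charges[1] = spec.Z, -spec.Z
    radii[0] = radii[1] = spec.np_radius

    rng = np.random.default_rng(seed)
    r_ion = spec.ion_radius
    lo = np.full(3, r_ion)
    hi = box - r_ion
    for j in range(2 * n_pairs):
        i = 2 + j
        placed = False
        for _ in range(max_tries_per_ion):
            trial = rng.uniform(lo, hi)
            d = np.linalg.norm(pos[:i] - trial, axis=1)
            if np.all(d >= radii[:i] + r_ion):
                pos[i] = trial
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not insert ion {j + 1}/{2 * n_pairs}: packing too dense"
            )
        is_cation = j < n_pairs
        charges[i] = spec.z if is_cation else -spec.z
        radii[i] = r_ion
        kinds.append("cation" if is_cation else "anion")

    cfg = Configuration(pos, charges, radii, kinds, box)
    assert abs(cfg.net_charge()) < 1e-12
    return cfg
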