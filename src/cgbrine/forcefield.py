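"""Interaction model for coarse-grained NaCl solutions.

The force field follows the SPICA family of CG models: nonbonded pairs
interact through Lennard-Jones potentials with a well depth of exactly
``-epsilon`` and a zero crossing at ``r = sigma`` —

* **LJ 9-6**  ``U(r) = (27/4) eps [ (s/r)^9  - (s/r)^6 ]``  (generic pairs)
* **LJ 12-4** ``U(r) = (3*sqrt(3)/2) eps [ (s/r)^12 - (s/r)^4 ]``
  (pairs involving the three-water bead and water–ion pairs)

plus a screened Coulomb term ``C q_i q_j / (eps_r r)`` with
``C = 332.0637 kcal·Å/(mol·e²)`` and a relative permittivity of 80 by
default.  Bonded terms are harmonic in the SPICA convention **without**
the 1/2 prefactor: ``U = k (x - x0)^2``; the choice is carried by an
explicit ``half_factor`` flag rather than left implicit.

Every pair that can occur in a system must be registered explicitly —
cross interactions are themselves optimization targets here, so silent
combination rules would corrupt fits.  A Lorentz–Berthelot fallback
exists but always warns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .units import COULOMB_K

LJ9_6 = "lj9_6"
LJ12_4 = "lj12_4"

_C96 = 27.0 / 4.0
_C124 = 3.0 * math.sqrt(3.0) / 2.0

CATEGORIES = ("water", "cation", "anion", "alkane", "headgroup", "other")


@dataclass(frozen=True)
class BeadType:
    """A CG bead species.

    ``waters_included`` counts the water molecules subsumed in the bead
    (3 for a SPICA-style water bead, 0 for a bare ion) so concentration
    and density bookkeeping can attribute the water content of solvated
    ion beads.
    """

    name: str
    mass: float  # amu
    charge: float = 0.0  # e
    category: str = "other"
    waters_included: int = 0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"bead {self.name!r}: mass must be > 0")
        if abs(self.charge) not in (0.0, 1.0):
            raise ValueError(f"bead {self.name!r}: |charge| must be 0 or 1")
        if self.category not in CATEGORIES:
            raise ValueError(f"bead {self.name!r}: unknown category {self.category!r}")
        if self.waters_included < 0:
            raise ValueError(f"bead {self.name!r}: waters_included must be >= 0")


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered type pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PairPotential:
    type_i: str
    type_j: str
    epsilon: float  # kcal/mol
    sigma: float  # Å
    form: str = LJ9_6

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.form not in (LJ9_6, LJ12_4):
            raise ValueError(f"unknown LJ form {self.form!r}")
        if self.type_i > self.type_j:  # canonical order: symmetric under swap
            a, b = self.type_i, self.type_j
            object.__setattr__(self, "type_i", b)
            object.__setattr__(self, "type_j", a)

    @property
    def key(self) -> tuple[str, str]:
        return pair_key(self.type_i, self.type_j)


@dataclass(frozen=True)
class BondSpec:
    """Harmonic bond U = k (r - r0)^2 (SPICA convention, no 1/2)."""

    type_i: str
    type_j: str
    k: float  # kcal/mol/Å²
    r0: float  # Å

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")

    @property
    def key(self) -> tuple[str, str]:
        return pair_key(self.type_i, self.type_j)


@dataclass(frozen=True)
class AngleSpec:
    """Harmonic angle U = k (theta - theta0)^2 with theta in radians.

    ``corr_enabled`` switches on the repulsive 1–3 LJ correction that
    prevents angle collapse in soft CG chains.
    """

    type_i: str
    type_j: str
    type_k: str
    k_theta: float  # kcal/mol/rad²
    theta0: float  # degrees
    corr_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.theta0 <= 180.0):
            raise ValueError("theta0 must be in (0, 180] degrees")

    @property
    def key(self) -> tuple[str, str, str]:
        a = (self.type_i, self.type_j, self.type_k)
        return min(a, a[::-1])


@dataclass
class BondedParams:
    bonds: dict[tuple[str, str], BondSpec] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], AngleSpec] = field(default_factory=dict)
    half_factor: bool = False  # True -> U = (1/2) k x²

    def add_bond(self, b: BondSpec) -> None:
        self.bonds[b.key] = b

    def add_angle(self, a: AngleSpec) -> None:
        self.angles[a.key] = a

    def bond(self, ti: str, tj: str) -> BondSpec:
        return self.bonds[pair_key(ti, tj)]

    def angle(self, ti: str, tj: str, tk: str) -> AngleSpec:
        a = (ti, tj, tk)
        return self.angles[min(a, a[::-1])]


@dataclass(frozen=True)
class ElectrostaticsSpec:
    relative_permittivity: float = 80.0
    method: str = "ewald"  # or "cutoff_shifted"
    real_space_cutoff: float = 15.0  # Å

    def __post_init__(self) -> None:
        if self.relative_permittivity < 1:
            raise ValueError("relative_permittivity must be >= 1")
        if self.real_space_cutoff <= 0:
            raise ValueError("real_space_cutoff must be > 0")
        if self.method not in ("ewald", "cutoff_shifted"):
            raise ValueError(f"unknown electrostatics method {self.method!r}")


@dataclass(frozen=True)
class ScalingFactors:
    """Uniform LJ rescaling eps' = kappa_eps * eps, sigma' = kappa_sigma * sigma
    applied to a selected family of cross pairs (e.g. ion–alkane)."""

    kappa_epsilon: float
    kappa_sigma: float
    # each selector term is a type name or "@category"
    target_species: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.kappa_epsilon <= 0 or self.kappa_sigma <= 0:
            raise ValueError("scaling factors must be > 0")


def _matches(sel: str, bt: BeadType) -> bool:
    if sel.startswith("@"):
        return bt.category == sel[1:]
    return bt.name == sel


# ---------------------------------------------------------------------------
# pairwise energy / force kernels
# ---------------------------------------------------------------------------

def pair_energy_force(r, p: PairPotential, cutoff: float | None = None):
    """LJ energy (kcal/mol) and radial force -dU/dr (kcal/mol/Å) at separation r.

    Accepts scalars or arrays.  Beyond ``cutoff`` both are exactly zero;
    the potential is plainly truncated here (the engine applies its own
    energy shift for conservation).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("overlapping beads: r must be > 0")
    sr = p.sigma / r
    if p.form == LJ9_6:
        u = _C96 * p.epsilon * (sr**9 - sr**6)
        f = _C96 * p.epsilon * (9.0 * sr**9 - 6.0 * sr**6) / r
    else:
        u = _C124 * p.epsilon * (sr**12 - sr**4)
        f = _C124 * p.epsilon * (12.0 * sr**12 - 4.0 * sr**4) / r
    if cutoff is not None:
        mask = r <= cutoff
        u = np.where(mask, u, 0.0)
        f = np.where(mask, f, 0.0)
    if u.ndim == 0:
        return float(u), float(f)
    return u, f


def coulomb_energy_force(r, q_i: float, q_j: float, es: ElectrostaticsSpec,
                         term: str = "auto"):
    """Real-space Coulomb contribution between two charges.

    ``term='bare'`` gives the plain screened interaction
    ``C q_i q_j / (eps_r r)``.  ``term='auto'`` follows the configured
    method: force-shifted truncation for ``cutoff_shifted`` (energy and
    force both reach zero at the cutoff), and the bare term for
    ``ewald`` (whose reciprocal-space remainder is not pairwise and is
    handled by the engine).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("overlapping beads: r must be > 0")
    pref = COULOMB_K * q_i * q_j / es.relative_permittivity
    if pref == 0.0:
        z = np.zeros_like(r)
        return (0.0, 0.0) if r.ndim == 0 else (z, z.copy())
    if term == "bare" or (term == "auto" and es.method == "ewald"):
        u = pref / r
        f = pref / r**2
    else:
        rc = es.real_space_cutoff
        u = pref * (1.0 / r - 1.0 / rc + (r - rc) / rc**2)
        f = pref * (1.0 / r**2 - 1.0 / rc**2)
        mask = r <= rc
        u = np.where(mask, u, 0.0)
        f = np.where(mask, f, 0.0)
    if u.ndim == 0:
        return float(u), float(f)
    return u, f


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def bonded_energy_force(positions: np.ndarray, box: np.ndarray, topology,
                        bp: BondedParams, pair_lookup=None,
                        return_virial: bool = False):
    """Total bonded energy and per-bead forces for a frame geometry.

    ``topology`` must expose ``bonds``/``angles`` index arrays and the
    per-entry type keys (see :class:`cgbrine.system.Topology`).  When an
    angle has ``corr_enabled`` and ``pair_lookup`` is given, a purely
    repulsive (WCA-capped) LJ term between the 1–3 beads is added to keep
    soft CG angles from collapsing.

    Degenerate angle geometries (an arm of near-zero length or an exactly
    collinear triple) are force-regularized rather than raising.
    """
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    n = len(positions)
    forces = np.zeros((n, 3))
    virial = np.zeros((3, 3))
    energy = 0.0
    pref = 0.5 if bp.half_factor else 1.0

    for (i, j), key in zip(topology.bonds, topology.bond_types):
        spec = bp.bonds[key]
        d = _min_image(positions[j] - positions[i], box)
        r = float(np.linalg.norm(d))
        if r < 1e-10:
            raise ValueError(f"zero-length bond between beads {i} and {j}")
        dr = r - spec.r0
        energy += pref * spec.k * dr * dr
        fmag = -2.0 * pref * spec.k * dr  # along d, acting on j
        fvec = fmag * d / r
        forces[j] += fvec
        forces[i] -= fvec
        virial += np.outer(d, fvec)

    for (i, j, k), key in zip(topology.angles, topology.angle_types):
        spec = bp.angles[key]
        a = _min_image(positions[i] - positions[j], box)
        b = _min_image(positions[k] - positions[j], box)
        ra = float(np.linalg.norm(a))
        rb = float(np.linalg.norm(b))
        if ra < 1e-8 or rb < 1e-8:
            warnings.warn(f"degenerate angle {i}-{j}-{k}: zero-length arm; force regularized")
            continue
        cos_t = float(np.dot(a, b) / (ra * rb))
        cos_t = max(-1.0, min(1.0, cos_t))
        theta = math.acos(cos_t)
        theta0 = math.radians(spec.theta0)
        dth = theta - theta0
        energy += pref * spec.k_theta * dth * dth
        sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 1e-12))
        coef = 2.0 * pref * spec.k_theta * dth / sin_t
        # dcos/dri etc.
        dcos_di = (b / (ra * rb)) - cos_t * a / (ra * ra)
        dcos_dk = (a / (ra * rb)) - cos_t * b / (rb * rb)
        fi = coef * dcos_di
        fk = coef * dcos_dk
        forces[i] += fi
        forces[k] += fk
        forces[j] -= fi + fk
        # atom-based virial relative to the apex (forces sum to zero)
        virial += np.outer(a, fi) + np.outer(b, fk)

        if spec.corr_enabled and pair_lookup is not None:
            p13 = pair_lookup(topology.type_of(i), topology.type_of(k))
            if p13 is not None:
                d13 = _min_image(positions[k] - positions[i], box)
                r13 = float(np.linalg.norm(d13))
                rmin = _lj_rmin(p13)
                if 0 < r13 < rmin:
                    u, f = pair_energy_force(r13, p13)
                    umin, _ = pair_energy_force(rmin, p13)
                    energy += u - umin  # shifted to zero at the LJ minimum
                    fvec = f * d13 / r13
                    forces[k] += fvec
                    forces[i] -= fvec
                    virial += np.outer(d13, fvec)

    if return_virial:
        return energy, forces, virial
    return energy, forces


def _lj_rmin(p: PairPotential) -> float:
    if p.form == LJ9_6:
        return (1.5) ** (1.0 / 3.0) * p.sigma
    return 3.0 ** 0.125 * p.sigma


# ---------------------------------------------------------------------------
# the force-field table
# ---------------------------------------------------------------------------

@dataclass
class ForceFieldTable:
    """Bead types, explicit pair potentials, bonded terms and electrostatics.

    This is the object the optimization loop mutates: pair entries can be
    replaced individually and the table serializes losslessly to a
    sectioned text format (:meth:`to_text` / :meth:`from_text`).
    """

    bead_types: dict[str, BeadType] = field(default_factory=dict)
    pairs: dict[tuple[str, str], PairPotential] = field(default_factory=dict)
    bonded: BondedParams = field(default_factory=BondedParams)
    electrostatics: ElectrostaticsSpec = field(default_factory=ElectrostaticsSpec)
    allow_lorentz_berthelot: bool = False

    # -- construction -----------------------------------------------------
    def add_bead(self, bt: BeadType) -> None:
        self.bead_types[bt.name] = bt

    def add_pair(self, p: PairPotential) -> None:
        self.pairs[p.key] = p

    # -- lookup -----------------------------------------------------------
    def pair(self, a: str, b: str) -> PairPotential:
        key = pair_key(a, b)
        try:
            return self.pairs[key]
        except KeyError:
            if self.allow_lorentz_berthelot:
                pa = self.pairs.get(pair_key(a, a))
                pb = self.pairs.get(pair_key(b, b))
                if pa is not None and pb is not None:
                    warnings.warn(
                        f"pair {key} missing: falling back to Lorentz–Berthelot "
                        "combination (explicit entries are strongly preferred)")
                    return PairPotential(key[0], key[1],
                                         math.sqrt(pa.epsilon * pb.epsilon),
                                         0.5 * (pa.sigma + pb.sigma),
                                         form=pa.form)
            raise KeyError(f"no pair potential registered for {key}") from None

    def get_pair(self, a: str, b: str) -> PairPotential | None:
        return self.pairs.get(pair_key(a, b))

    def charge(self, name: str) -> float:
        return self.bead_types[name].charge

    def mass(self, name: str) -> float:
        return self.bead_types[name].mass

    # -- transformation ---------------------------------------------------
    def replace_pair(self, a: str, b: str, *, epsilon: float | None = None,
                     sigma: float | None = None) -> "ForceFieldTable":
        """Return a copy with one pair entry modified; all else untouched."""
        key = pair_key(a, b)
        if key not in self.pairs:
            raise KeyError(f"no pair potential registered for {key}")
        new = self.copy()
        old = new.pairs[key]
        new.pairs[key] = replace(
            old,
            epsilon=old.epsilon if epsilon is None else epsilon,
            sigma=old.sigma if sigma is None else sigma,
        )
        return new

    def copy(self) -> "ForceFieldTable":
        return ForceFieldTable(
            bead_types=dict(self.bead_types),
            pairs=dict(self.pairs),
            bonded=BondedParams(dict(self.bonded.bonds), dict(self.bonded.angles),
                                self.bonded.half_factor),
            electrostatics=self.electrostatics,
            allow_lorentz_berthelot=self.allow_lorentz_berthelot,
        )

    # -- serialization ----------------------------------------------------
    def to_text(self) -> str:
        lines: list[str] = ["# cgbrine force-field table v1"]
        for bt in self.bead_types.values():
            lines += ["[bead_type]",
                      f"name = {bt.name}",
                      f"mass = {bt.mass!r}",
                      f"charge = {bt.charge!r}",
                      f"category = {bt.category}",
                      f"waters_included = {bt.waters_included}"]
        for p in self.pairs.values():
            lines += ["[pair]",
                      f"types = {p.key[0]} {p.key[1]}",
                      f"epsilon = {p.epsilon!r}",
                      f"sigma = {p.sigma!r}",
                      f"form = {p.form}"]
        for b in self.bonded.bonds.values():
            lines += ["[bond]",
                      f"types = {b.key[0]} {b.key[1]}",
                      f"k = {b.k!r}",
                      f"r0 = {b.r0!r}"]
        for a in self.bonded.angles.values():
            lines += ["[angle]",
                      f"types = {a.type_i} {a.type_j} {a.type_k}",
                      f"k_theta = {a.k_theta!r}",
                      f"theta0 = {a.theta0!r}",
                      f"corr_enabled = {a.corr_enabled}"]
        es = self.electrostatics
        lines += ["[electrostatics]",
                  f"relative_permittivity = {es.relative_permittivity!r}",
                  f"method = {es.method}",
                  f"real_space_cutoff = {es.real_space_cutoff!r}"]
        lines += ["[options]",
                  f"half_factor = {self.bonded.half_factor}",
                  f"allow_lorentz_berthelot = {self.allow_lorentz_berthelot}"]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ForceFieldTable":
        ff = cls(electrostatics=ElectrostaticsSpec())
        section: str | None = None
        fields: dict[str, str] = {}

        def flush() -> None:
            nonlocal section, fields
            if section is None:
                return
            f = fields
            if section == "bead_type":
                ff.add_bead(BeadType(f["name"], float(f["mass"]), float(f["charge"]),
                                     f["category"], int(f["waters_included"])))
            elif section == "pair":
                ti, tj = f["types"].split()
                ff.add_pair(PairPotential(ti, tj, float(f["epsilon"]),
                                          float(f["sigma"]), f["form"]))
            elif section == "bond":
                ti, tj = f["types"].split()
                ff.bonded.add_bond(BondSpec(ti, tj, float(f["k"]), float(f["r0"])))
            elif section == "angle":
                ti, tj, tk = f["types"].split()
                ff.bonded.add_angle(AngleSpec(ti, tj, tk, float(f["k_theta"]),
                                              float(f["theta0"]),
                                              f["corr_enabled"] == "True"))
            elif section == "electrostatics":
                ff.electrostatics = ElectrostaticsSpec(
                    float(f["relative_permittivity"]), f["method"],
                    float(f["real_space_cutoff"]))
            elif section == "options":
                ff.bonded.half_factor = f["half_factor"] == "True"
                ff.allow_lorentz_berthelot = f["allow_lorentz_berthelot"] == "True"
            section, fields = None, {}

        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                flush()
                section = line.strip("[]")
            else:
                k, _, v = line.partition("=")
                fields[k.strip()] = v.strip()
        flush()
        return ff

    def __eq__(self, other) -> bool:  # structural equality, exact floats
        if not isinstance(other, ForceFieldTable):
            return NotImplemented
        return (self.bead_types == other.bead_types
                and self.pairs == other.pairs
                and self.bonded.bonds == other.bonded.bonds
                and self.bonded.angles == other.bonded.angles
                and self.bonded.half_factor == other.bonded.half_factor
                and self.electrostatics == other.electrostatics)


def apply_scaling(ff: ForceFieldTable, s: ScalingFactors) -> ForceFieldTable:
    """Scale eps/sigma of every pair matched by ``s.target_species``.

    Raises if the selector matches nothing — a silent no-op would hide a
    mis-specified selector in a fitting pipeline.
    """
    new = ff.copy()
    hit = 0
    for key, p in list(new.pairs.items()):
        ba, bb = ff.bead_types[p.type_i], ff.bead_types[p.type_j]
        matched = any(
            (_matches(sa, ba) and _matches(sb, bb))
            or (_matches(sa, bb) and _matches(sb, ba))
            for sa, sb in s.target_species)
        if matched:
            new.pairs[key] = replace(p, epsilon=s.kappa_epsilon * p.epsilon,
                                     sigma=s.kappa_sigma * p.sigma)
            hit += 1
    if hit == 0:
        raise ValueError(f"scaling selector {s.target_species} matched no pairs")
    return new


@dataclass
class ValidationFinding:
    kind: str  # "missing_pair" | "invalid_parameter" | "missing_bead"
    detail: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __str__(self) -> str:
        if self.ok:
            return "force-field table complete"
        return "\n".join(f"{f.kind}: {f.detail}" for f in self.findings)


def validate_table(ff: ForceFieldTable, system_composition: Iterable[str]) -> ValidationReport:
    """Check the table covers a composition (sequence of bead type names)."""
    rep = ValidationReport()
    present = sorted(set(system_composition))
    for name in present:
        if name not in ff.bead_types:
            rep.findings.append(ValidationFinding("missing_bead", name))
    known = [n for n in present if n in ff.bead_types]
    for ai in range(len(known)):
        for bi in range(ai, len(known)):
            key = pair_key(known[ai], known[bi])
            if key not in ff.pairs:
                rep.findings.append(
                    ValidationFinding("missing_pair", f"{key[0]}-{key[1]}"))
    for key, p in ff.pairs.items():
        # dataclass validators catch construction-time errors; injected
        # values (e.g. via __dict__ surgery in a fit) are re-checked here
        if not (p.epsilon > 0) or not (p.sigma > 0):
            rep.findings.append(ValidationFinding(
                "invalid_parameter", f"pair {key}: epsilon={p.epsilon}, sigma={p.sigma}"))
    return rep
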