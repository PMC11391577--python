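"""Desk-scale CG-MD engine: forces, ensembles, virtual walls.

Propagates systems with velocity Verlet at a 10 fs default time step,
Nosé–Hoover chain thermostats (length 3) and MTK-style Nosé–Hoover
barostats, either isotropic (NPT) or acting on the z axis only with the
lateral area fixed (NPzAT).  Nonbonded interactions use a 15 Å cutoff
with an energy shift; electrostatics are Ewald by default with a
force-shifted cutoff mode for fast exploratory runs.

Semipermeable virtual walls act one-sidedly on selected bead types only
(ions), with a quadratic indenter force law F = k·Δx² by default
(k in kcal/mol/Å³) and a linear half-harmonic alternative; per-wall
forces are recorded on every sampled frame so the osmotic-pressure
estimator can consume them.

Units are Å / fs / amu / kcal/mol internally; pressures cross the API
boundary in bar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import ewald as _ewald
from ._kernels import (COUL_EWALD_REAL, COUL_NONE, COUL_SHIFTED, nb_kernel)
from .forcefield import (LJ9_6, ForceFieldTable, _matches,
                         bonded_energy_force, pair_energy_force, validate_table)
from .system import Frame, SystemBundle, Topology, Trajectory
from .units import (KB, KCAL_MOL_A3_TO_BAR, KCAL_MOL_TO_INTERNAL, MVV_TO_KCAL,
                    COULOMB_K, kinetic_temperature, thermal_sigma)

_C96 = 27.0 / 4.0
_C124 = 3.0 * math.sqrt(3.0) / 2.0

HARD_FLOOR = 0.1  # Å — below this, beads are considered overlapping


class OverlapError(RuntimeError):
    pass


class IntegrationBlowupError(RuntimeError):
    def __init__(self, message: str, frame: Frame | None = None):
        super().__init__(message)
        self.frame = frame


@dataclass(frozen=True)
class WallSpec:
    """One-sided repulsive wall acting on selected bead types.

    ``side='+'`` repels beads whose coordinate exceeds ``position``
    (penetration Δ = x - position); ``side='-'`` the mirror case.
    ``force_law='indent_quadratic'`` gives a per-bead restoring force
    k·Δ² (k in kcal/mol/Å³); ``'half_harmonic_linear'`` gives k·Δ
    (k then read as kcal/mol/Å²).
    """

    axis: str  # 'x' | 'y' | 'z'
    position: float  # Å
    side: str  # '+' | '-'
    k: float = 20.0
    affected: tuple[str, ...] = ("@cation", "@anion")
    force_law: str = "indent_quadratic"

    def __post_init__(self) -> None:
        if self.axis not in "xyz":
            raise ValueError("axis must be x, y or z")
        if self.side not in "+-":
            raise ValueError("side must be '+' or '-'")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not self.affected:
            raise ValueError("affected selector must be non-empty")
        if self.force_law not in ("indent_quadratic", "half_harmonic_linear"):
            raise ValueError(f"unknown force_law {self.force_law!r}")

    @property
    def axis_index(self) -> int:
        return "xyz".index(self.axis)


@dataclass
class PressureTensor:
    """Diagonal + off-diagonal pressure components in bar."""

    tensor: np.ndarray  # (3, 3)

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("pressure tensor must be finite")

    @property
    def P_xx(self) -> float:
        return float(self.tensor[0, 0])

    @property
    def P_yy(self) -> float:
        return float(self.tensor[1, 1])

    @property
    def P_zz(self) -> float:
        return float(self.tensor[2, 2])

    @property
    def scalar(self) -> float:
        return float(np.trace(self.tensor) / 3.0)


@dataclass(frozen=True)
class EnsembleSpec:
    kind: str  # NVE | NVT | NPT_iso | NPzAT
    temperature: float = 298.0  # K
    pressure: float = 1.0  # bar
    dt: float = 10.0  # fs
    tau_t: float | None = None  # fs, default 100*dt
    tau_p: float | None = None  # fs, default 1000*dt
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("NVE", "NVT", "NPT_iso", "NPzAT"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.kind != "NVE" and self.temperature <= 0:
            raise ValueError("temperature must be > 0 for thermostatted ensembles")

    @property
    def thermostat_tau(self) -> float:
        return self.tau_t if self.tau_t is not None else 100.0 * self.dt

    @property
    def barostat_tau(self) -> float:
        return self.tau_p if self.tau_p is not None else 1000.0 * self.dt


@dataclass
class ForceResult:
    forces: np.ndarray  # kcal/mol/Å, (N, 3)
    potential_energy: float  # kcal/mol
    virial: np.ndarray  # kcal/mol, (3, 3) — Σ r⊗F over interactions
    wall_forces: np.ndarray  # per wall total |F| on the wall, kcal/mol/Å


# ---------------------------------------------------------------------------
# nonbonded bookkeeping
# ---------------------------------------------------------------------------

class NonbondedTables:
    """Per-type parameter matrices compiled from a ForceFieldTable."""

    def __init__(self, ff: ForceFieldTable, type_names: list[str],
                 lj_shift: bool = True, ewald_accuracy: float = 3.0):
        report = validate_table(ff, type_names)
        if not report.ok:
            raise ValueError(f"force-field table incomplete:\n{report}")
        self.ff = ff
        self.types = sorted(set(type_names))
        self.index = {t: i for i, t in enumerate(self.types)}
        self.tidx = np.array([self.index[t] for t in type_names], dtype=np.int64)
        nt = len(self.types)
        self.eps = np.zeros((nt, nt))
        self.sig = np.ones((nt, nt))
        self.form = np.zeros((nt, nt), dtype=np.int64)
        self.ushift = np.zeros((nt, nt))
        rc = ff.electrostatics.real_space_cutoff
        for a in range(nt):
            for b in range(nt):
                p = ff.pair(self.types[a], self.types[b])
                self.eps[a, b] = p.epsilon
                self.sig[a, b] = p.sigma
                self.form[a, b] = 0 if p.form == LJ9_6 else 1
                if lj_shift:
                    u_rc, _ = pair_energy_force(rc, p)
                    self.ushift[a, b] = u_rc
        self.q = np.array([ff.charge(t) for t in type_names], dtype=float)
        self.masses = np.array([ff.mass(t) for t in type_names], dtype=float)
        self.cutoff = rc
        es = ff.electrostatics
        self.coul_pref = COULOMB_K / es.relative_permittivity
        self.has_charges = bool(np.any(self.q != 0.0))
        if not self.has_charges:
            self.coul_mode = COUL_NONE
        elif es.method == "cutoff_shifted":
            self.coul_mode = COUL_SHIFTED
        else:
            self.coul_mode = COUL_EWALD_REAL
        self.ewald_accuracy = ewald_accuracy


def all_pairs(n: int, exclusions: set[tuple[int, int]] | None = None):
    pi, pj = np.triu_indices(n, k=1)
    if exclusions:
        mask = np.ones(len(pi), dtype=bool)
        excl = np.array(sorted(exclusions), dtype=np.int64)
        if len(excl):
            # pair id = i*n + j is unique for i<j
            pair_id = pi.astype(np.int64) * n + pj
            excl_id = excl[:, 0] * n + excl[:, 1]
            mask &= ~np.isin(pair_id, excl_id)
        pi, pj = pi[mask], pj[mask]
    return pi.astype(np.int64), pj.astype(np.int64)


def verlet_list(pos: np.ndarray, box: np.ndarray, rlist: float,
                exclusions: set[tuple[int, int]] | None = None):
    """Neighbor list: all periodic pairs within ``rlist`` (built O(N²),
    consumed O(N) per step until displacements exceed half the skin)."""
    n = len(pos)
    pi, pj = all_pairs(n, exclusions)
    d = pos[pj] - pos[pi]
    d -= box * np.round(d / box)
    within = np.einsum("ij,ij->i", d, d) <= rlist * rlist
    return pi[within], pj[within]


# ---------------------------------------------------------------------------
# walls
# ---------------------------------------------------------------------------

def _affected_mask(w: WallSpec, ff: ForceFieldTable, type_names: list[str]) -> np.ndarray:
    beads = [ff.bead_types[t] for t in type_names]
    return np.array([any(_matches(sel, b) for sel in w.affected) for b in beads])


def wall_contribution(positions: np.ndarray, w: WallSpec, mask: np.ndarray):
    """Per-bead forces, potential energy, and total force on the wall."""
    n = len(positions)
    forces = np.zeros((n, 3))
    x = positions[:, w.axis_index]
    if w.side == "+":
        pen = x - w.position
    else:
        pen = w.position - x
    pen = np.where(mask & (pen > 0), pen, 0.0)
    if w.force_law == "indent_quadratic":
        fmag = w.k * pen**2
        energy = float(np.sum(w.k * pen**3 / 3.0))
    else:
        fmag = w.k * pen
        energy = float(np.sum(0.5 * w.k * pen**2))
    sign = -1.0 if w.side == "+" else 1.0
    forces[:, w.axis_index] = sign * fmag
    return forces, energy, float(np.sum(fmag))


def wall_force(frame: Frame, w: WallSpec, ff: ForceFieldTable) -> float:
    """Instantaneous total force exerted on one wall (kcal/mol/Å)."""
    mask = _affected_mask(w, ff, frame.type_names)
    _, _, total = wall_contribution(frame.positions, w, mask)
    return total


# ---------------------------------------------------------------------------
# Nosé–Hoover chains
# ---------------------------------------------------------------------------

class NoseHooverChain:
    """Thermostat chain (default length 3), explicit half-step update."""

    def __init__(self, ndof: int, temperature: float, tau: float, length: int = 3):
        self.ndof = ndof
        self.kt = KB * temperature
        self.Q = np.empty(length)
        self.Q[0] = ndof * self.kt * tau**2
        self.Q[1:] = self.kt * tau**2
        self.vxi = np.zeros(length)

    def half_step(self, ke2: float, dt: float) -> float:
        """Advance the chain by dt/2 given 2×KE (kcal/mol); return the
        velocity scale factor to apply to the thermostatted dofs."""
        M = len(self.Q)
        G = np.zeros(M)
        G[0] = (ke2 - self.ndof * self.kt) / self.Q[0]
        for i in range(1, M):
            G[i] = (self.Q[i - 1] * self.vxi[i - 1] ** 2 - self.kt) / self.Q[i]
        self.vxi[M - 1] += G[M - 1] * dt / 4.0
        for i in range(M - 2, -1, -1):
            e = math.exp(-self.vxi[i + 1] * dt / 8.0)
            self.vxi[i] = (self.vxi[i] * e + G[i] * dt / 4.0) * e
        s = math.exp(-self.vxi[0] * dt / 2.0)
        ke2 *= s * s
        G[0] = (ke2 - self.ndof * self.kt) / self.Q[0]
        for i in range(M - 1):
            e = math.exp(-self.vxi[i + 1] * dt / 8.0)
            self.vxi[i] = (self.vxi[i] * e + G[i] * dt / 4.0) * e
            G[i + 1] = (self.Q[i] * self.vxi[i] ** 2 - self.kt) / self.Q[i + 1]
        self.vxi[M - 1] += G[M - 1] * dt / 4.0
        return s


# ---------------------------------------------------------------------------
# the simulation driver
# ---------------------------------------------------------------------------

class Simulation:
    """Stateful integrator over one system; prefer :func:`run` for the
    one-call interface."""

    def __init__(self, frame: Frame, ff: ForceFieldTable,
                 ensemble: EnsembleSpec, walls: list[WallSpec] | None = None,
                 topology: Topology | None = None,
                 nonbonded: str = "direct", skin: float = 2.0,
                 lj_shift: bool = True, ewald_accuracy: float = 3.0):
        if nonbonded not in ("direct", "neighbor"):
            raise ValueError("nonbonded must be 'direct' or 'neighbor'")
        self.frame = frame.copy()
        self.ff = ff
        self.ensemble = ensemble
        self.walls = list(walls or [])
        self.topology = topology if topology is not None else Topology(list(frame.type_names))
        self.tables = NonbondedTables(ff, frame.type_names, lj_shift=lj_shift,
                                      ewald_accuracy=ewald_accuracy)
        self.exclusions = self.topology.exclusion_pairs()
        self._excl_arr = np.array(sorted(self.exclusions), dtype=np.int64) \
            if self.exclusions else np.zeros((0, 2), dtype=np.int64)
        self.nonbonded = nonbonded
        self.skin = skin
        self._pairs: tuple[np.ndarray, np.ndarray] | None = None
        self._pairs_ref_pos: np.ndarray | None = None
        self._wall_masks = [_affected_mask(w, ff, frame.type_names) for w in self.walls]
        self.rng = np.random.default_rng(ensemble.seed)
        self.ndof = max(3 * frame.n_beads - 3, 1)
        self._thermo: NoseHooverChain | None = None
        self._baro_thermo: NoseHooverChain | None = None
        self.v_eps = 0.0
        if ensemble.kind in ("NVT", "NPT_iso", "NPzAT"):
            self._thermo = NoseHooverChain(self.ndof, ensemble.temperature,
                                           ensemble.thermostat_tau)
        if ensemble.kind in ("NPT_iso", "NPzAT"):
            self._baro_thermo = NoseHooverChain(1, ensemble.temperature,
                                                ensemble.barostat_tau)
            d = 3 if ensemble.kind == "NPT_iso" else 1
            self.W = (self.ndof + d) * KB * ensemble.temperature * ensemble.barostat_tau**2
        self._force_cache: ForceResult | None = None

    # -- forces -----------------------------------------------------------

    def _pair_list(self):
        pos = self.frame.positions
        if self.nonbonded == "direct":
            if self._pairs is None:
                self._pairs = all_pairs(self.frame.n_beads, self.exclusions)
            return self._pairs
        rebuild = self._pairs is None
        if not rebuild:
            disp = pos - self._pairs_ref_pos
            disp -= self.frame.box * np.round(disp / self.frame.box)
            if np.max(np.abs(disp)) > 0.5 * self.skin:
                rebuild = True
        if rebuild:
            self._pairs = verlet_list(pos, self.frame.box,
                                      self.tables.cutoff + self.skin, self.exclusions)
            self._pairs_ref_pos = pos.copy()
        return self._pairs

    def compute_forces(self) -> ForceResult:
        frame = self.frame
        t = self.tables
        pi, pj = self._pair_list()
        forces, energy, virial, min_r2, mi, mj = nb_kernel(
            frame.positions, frame.box, t.tidx, pi, pj, t.eps, t.sig, t.form,
            t.ushift, t.q, t.coul_pref, t.cutoff, t.coul_mode,
            t.ewald_accuracy / t.cutoff)
        if min_r2 < HARD_FLOOR**2:
            raise OverlapError(
                f"beads {mi} ({frame.type_names[mi]}) and {mj} "
                f"({frame.type_names[mj]}) overlap at r = {math.sqrt(min_r2):.4f} Å")
        if t.coul_mode == COUL_EWALD_REAL:
            params = _ewald.EwaldParams.for_box(frame.box, t.cutoff, t.ewald_accuracy)
            e_rec, f_rec, w_rec = _ewald.reciprocal(frame.positions, t.q, frame.box,
                                                    params, t.coul_pref)
            energy += e_rec + _ewald.self_energy(t.q, params, t.coul_pref)
            energy += _ewald.background_energy(t.q, frame.box, params, t.coul_pref)
            forces += f_rec
            virial += w_rec
            if len(self._excl_arr):
                e_c, f_c, w_c = _ewald.exclusion_correction(
                    frame.positions, t.q, frame.box, self._excl_arr, params, t.coul_pref)
                energy += e_c
                forces += f_c
                virial += w_c
        if len(self.topology.bonds) or len(self.topology.angles):
            e_b, f_b, w_b = bonded_energy_force(
                frame.positions, frame.box, self.topology, self.ff.bonded,
                pair_lookup=self.ff.get_pair, return_virial=True)
            energy += e_b
            forces += f_b
            virial += w_b
        wall_totals = np.zeros(len(self.walls))
        for wi, (w, mask) in enumerate(zip(self.walls, self._wall_masks)):
            f_w, e_w, tot = wall_contribution(frame.positions, w, mask)
            forces += f_w
            energy += e_w
            wall_totals[wi] = tot
        return ForceResult(forces, energy, virial, wall_totals)

    # -- kinetics ---------------------------------------------------------

    def kinetic_tensor(self) -> np.ndarray:
        v = self.frame.velocities
        m = self.tables.masses
        return MVV_TO_KCAL * np.einsum("i,ia,ib->ab", m, v, v)

    def kinetic_energy(self) -> float:
        return float(np.trace(self.kinetic_tensor()) / 2.0)

    def temperature(self) -> float:
        return kinetic_temperature(self.kinetic_energy(), self.ndof)

    def pressure(self, virial: np.ndarray) -> PressureTensor:
        return pressure_tensor_from(self.kinetic_tensor(), virial, self.frame.volume)

    # -- integration ------------------------------------------------------

    def initialize_velocities(self, temperature: float | None = None) -> None:
        """Maxwell–Boltzmann draw, COM drift removed, then rescaled to the
        exact setpoint per axis.  Per-axis equipartition matters for
        weakly/non-interacting reference systems, where axes never mix."""
        T = temperature if temperature is not None else self.ensemble.temperature
        m = self.tables.masses
        v = self.rng.normal(size=(self.frame.n_beads, 3))
        v *= np.array([thermal_sigma(T, mi) for mi in m])[:, None]
        p = (m[:, None] * v).sum(axis=0) / m.sum()
        v -= p[None, :]
        ke_target_axis = 0.5 * (self.ndof / 3.0) * KB * T
        for ax in range(3):
            ke_ax = 0.5 * MVV_TO_KCAL * float(np.sum(m * v[:, ax] ** 2))
            if ke_ax > 0:
                v[:, ax] *= math.sqrt(ke_target_axis / ke_ax)
        self.frame.velocities = v

    def _accel(self, forces: np.ndarray) -> np.ndarray:
        return forces * KCAL_MOL_TO_INTERNAL / self.tables.masses[:, None]

    def step(self) -> None:
        kind = self.ensemble.kind
        dt = self.ensemble.dt
        frame = self.frame
        if self._force_cache is None:
            self._force_cache = self.compute_forces()
        fr = self._force_cache

        if kind in ("NVE", "NVT"):
            if kind == "NVT":
                s = self._thermo.half_step(2.0 * self.kinetic_energy(), dt)
                frame.velocities *= s
            frame.velocities += 0.5 * dt * self._accel(fr.forces)
            frame.positions += dt * frame.velocities
            frame.time += dt
            self._force_cache = self.compute_forces()
            frame.velocities += 0.5 * dt * self._accel(self._force_cache.forces)
            if kind == "NVT":
                s = self._thermo.half_step(2.0 * self.kinetic_energy(), dt)
                frame.velocities *= s
        else:
            self._npt_step(fr, dt, z_only=(kind == "NPzAT"))

        if not (np.all(np.isfinite(frame.positions))
                and np.all(np.isfinite(frame.velocities))):
            raise IntegrationBlowupError(
                "non-finite coordinates or velocities encountered", frame)

    def _coupled_pressure(self, virial: np.ndarray, z_only: bool) -> float:
        p = pressure_tensor_from(self.kinetic_tensor(), virial, self.frame.volume)
        if z_only:
            return p.P_zz
        return p.scalar

    def _npt_step(self, fr: ForceResult, dt: float, z_only: bool) -> None:
        frame = self.frame
        ens = self.ensemble
        d = 1 if z_only else 3
        p0 = ens.pressure / KCAL_MOL_A3_TO_BAR  # kcal/mol/Å³
        alpha_f = 1.0 + d / self.ndof
        axes = [2] if z_only else [0, 1, 2]

        def thermo_half():
            s = self._thermo.half_step(2.0 * self.kinetic_energy(), dt)
            frame.velocities *= s
            sb = self._baro_thermo.half_step(self.W * self.v_eps**2, dt)
            self.v_eps *= sb

        def veps_half(virial):
            V = frame.volume
            p_int = self._coupled_pressure(virial, z_only)
            p_int_internal = p_int / KCAL_MOL_A3_TO_BAR
            G = (d * V * (p_int_internal - p0)
                 + (d / self.ndof) * 2.0 * self.kinetic_energy()) / self.W
            self.v_eps += 0.5 * dt * G

        thermo_half()
        veps_half(fr.virial)
        # velocity half-kick with cell coupling
        decay = math.exp(-0.5 * dt * alpha_f * self.v_eps)
        a = self._accel(fr.forces)
        for ax in axes:
            frame.velocities[:, ax] = (frame.velocities[:, ax] * decay
                                       + 0.5 * dt * a[:, ax]
                                       * math.exp(-0.25 * dt * alpha_f * self.v_eps))
        for ax in (set([0, 1, 2]) - set(axes)):
            frame.velocities[:, ax] += 0.5 * dt * a[:, ax]
        # drift + cell scaling
        growth = math.exp(dt * self.v_eps)
        half_growth = math.exp(0.5 * dt * self.v_eps)
        for ax in axes:
            frame.positions[:, ax] = (frame.positions[:, ax] * growth
                                      + dt * frame.velocities[:, ax] * half_growth)
            frame.box[ax] *= growth
        for ax in (set([0, 1, 2]) - set(axes)):
            frame.positions[:, ax] += dt * frame.velocities[:, ax]
        frame.time += dt
        if self.nonbonded == "neighbor":
            self._pairs = None  # box changed; rebuild
        self._force_cache = self.compute_forces()
        a = self._accel(self._force_cache.forces)
        for ax in axes:
            frame.velocities[:, ax] = (frame.velocities[:, ax]
                                       + 0.5 * dt * a[:, ax]
                                       * math.exp(-0.25 * dt * alpha_f * self.v_eps)) \
                * math.exp(-0.5 * dt * alpha_f * self.v_eps)
        for ax in (set([0, 1, 2]) - set(axes)):
            frame.velocities[:, ax] += 0.5 * dt * a[:, ax]
        veps_half(self._force_cache.virial)
        thermo_half()

    def run(self, n_steps: int, sample_every: int = 10) -> Trajectory:
        if n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        traj = Trajectory(sampling_interval=sample_every * self.ensemble.dt)
        self._force_cache = self.compute_forces()
        self._record(traj)
        for istep in range(1, n_steps + 1):
            self.step()
            if istep % sample_every == 0:
                self._record(traj)
        return traj

    def _record(self, traj: Trajectory) -> None:
        fr = self._force_cache
        ke = self.kinetic_energy()
        ptens = self.pressure(fr.virial)
        traj.append(self.frame.wrapped(), fr.potential_energy, ke,
                    kinetic_temperature(ke, self.ndof), ptens.tensor,
                    fr.wall_forces.copy())

    # -- minimization -----------------------------------------------------

    def minimize(self, max_steps: int = 200, max_disp: float = 0.2,
                 ftol: float = 1e-3) -> float:
        """Displacement-capped steepest descent to relax packing contacts."""
        fr = self.compute_forces()
        for _ in range(max_steps):
            fmax = float(np.max(np.abs(fr.forces)))
            if fmax < ftol:
                break
            step = min(max_disp / fmax, 1e-2) * fr.forces
            np.clip(step, -max_disp, max_disp, out=step)
            trial = self.frame.positions + step
            old = self.frame.positions
            self.frame.positions = trial
            try:
                new_fr = self.compute_forces()
            except OverlapError:
                self.frame.positions = old
                break
            if new_fr.potential_energy > fr.potential_energy:
                self.frame.positions = old
                max_disp *= 0.5
                if max_disp < 1e-4:
                    break
                continue
            fr = new_fr
        self._force_cache = fr
        return fr.potential_energy


# ---------------------------------------------------------------------------
# functional façade
# ---------------------------------------------------------------------------

def pressure_tensor_from(kinetic_tensor: np.ndarray, virial: np.ndarray,
                         volume: float) -> PressureTensor:
    """P_ab = (Σ m v_a v_b + W_ab)/V, reported in bar."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return PressureTensor((kinetic_tensor + virial) / volume * KCAL_MOL_A3_TO_BAR)


def pressure_tensor(frame: Frame, virial: np.ndarray, masses: np.ndarray) -> PressureTensor:
    kin = MVV_TO_KCAL * np.einsum("i,ia,ib->ab", np.asarray(masses, float),
                                  frame.velocities, frame.velocities)
    return pressure_tensor_from(kin, virial, frame.volume)


def compute_forces(frame: Frame, ff: ForceFieldTable,
                   walls: list[WallSpec] | None = None,
                   topology: Topology | None = None,
                   nonbonded: str = "direct") -> ForceResult:
    sim = Simulation(frame, ff, EnsembleSpec("NVE"), walls=walls,
                     topology=topology, nonbonded=nonbonded)
    return sim.compute_forces()


def step(frame: Frame, ff: ForceFieldTable, ensemble: EnsembleSpec,
         walls: list[WallSpec] | None = None,
         topology: Topology | None = None) -> Frame:
    """Single-step convenience wrapper (stateless; use :class:`Simulation`
    or :func:`run` for multi-step work)."""
    sim = Simulation(frame, ff, ensemble, walls=walls, topology=topology)
    sim.step()
    return sim.frame


def run(system: SystemBundle, ff: ForceFieldTable, ensemble: EnsembleSpec,
        n_steps: int, sample_every: int = 10,
        walls: list[WallSpec] | None = None, nonbonded: str = "direct",
        initialize_velocities: bool = False,
        minimize_first: bool = False) -> Trajectory:
    """Propagate a SystemBundle and return the sampled Trajectory.

    Bitwise reproducible for a fixed ``ensemble.seed`` and thread
    configuration.  ``walls`` defaults to the bundle's own walls.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    use_walls = walls if walls is not None else system.walls
    sim = Simulation(system.frame, ff, ensemble, walls=use_walls,
                     topology=system.topology, nonbonded=nonbonded)
    if minimize_first:
        sim.minimize()
    if initialize_velocities or not np.any(system.frame.velocities):
        if ensemble.kind != "NVE" or initialize_velocities:
            sim.initialize_velocities()
    return sim.run(n_steps, sample_every)
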