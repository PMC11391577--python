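"""Reduced end-to-end measurement protocols.

Each function mirrors one of the study protocols — bulk NPT for density,
z-tripled slab NVT for surface tension, biphasic NPzAT for interfacial
tension, walled NVT cell for osmotic pressure — at desk scale: the
default bead counts and run lengths are chosen so a single property
evaluation takes seconds, which is what makes the optimization loop
usable interactively.  Full-length windows (2 ns equilibration / 20 ns
production, last 5 ns statistics) remain plain arguments.

Every protocol is deterministic for a fixed seed, which is what lets
ground-truth recovery tests drive the objective to exactly zero at the
true parameters.
"""

from __future__ import annotations

import numpy as np

from . import observables as obs
from .engine import EnsembleSpec, IntegrationBlowupError, OverlapError, Simulation
from .forcefield import ForceFieldTable
from .system import CompositionSpec
from .sysgen import make_bulk, make_osmotic, make_slab


def _masses(ff: ForceFieldTable, type_names) -> np.ndarray:
    return np.array([ff.mass(t) for t in type_names])


def simulate_density(ff: ForceFieldTable, molarity: float,
                     ion_model: str = "solvated", seed: int = 0,
                     total_beads: int = 150, n_steps: int = 600,
                     sample_every: int = 5, dt: float = 8.0,
                     temperature: float = 293.0, pressure: float = 1.0,
                     window: float = 0.25) -> obs.ObservableResult:
    """Bulk NPT density at one concentration (kg/m³)."""
    bundle = make_bulk(molarity, ion_model, total_beads=total_beads, seed=seed)
    ens = EnsembleSpec("NPT_iso", temperature=temperature, pressure=pressure,
                       dt=dt, seed=seed)
    sim = Simulation(bundle.frame, ff, ens, topology=bundle.topology)
    sim.minimize(max_steps=50)
    sim.initialize_velocities()
    traj = sim.run(n_steps, sample_every)
    return obs.mass_density(traj, _masses(ff, bundle.frame.type_names),
                            window=window)


def simulate_surface_tension(ff: ForceFieldTable, molarity: float,
                             ion_model: str = "solvated", seed: int = 0,
                             total_beads: int = 150, n_steps: int = 600,
                             sample_every: int = 5, dt: float = 8.0,
                             temperature: float = 293.0,
                             equil_steps: int = 150,
                             window: float = 0.25) -> obs.ObservableResult:
    """Slab NVT surface tension at one concentration (mN/m).

    Builds the bulk box, relaxes it briefly in the NVT ensemble, triples
    the box along z and runs NVT production on the resulting slab.
    """
    bundle = make_bulk(molarity, ion_model, total_beads=total_beads, seed=seed)
    ens = EnsembleSpec("NVT", temperature=temperature, dt=dt, seed=seed)
    sim = Simulation(bundle.frame, ff, ens, topology=bundle.topology)
    sim.minimize(max_steps=50)
    sim.initialize_velocities()
    sim.run(equil_steps, max(equil_steps, 1))
    slab = make_slab(sim.frame)
    sim2 = Simulation(slab, ff, EnsembleSpec("NVT", temperature=temperature,
                                             dt=dt, seed=seed + 1),
                      topology=bundle.topology)
    traj = sim2.run(n_steps, sample_every)
    return obs.surface_tension(traj, window=window)


def simulate_osmotic_pressure(ff: ForceFieldTable, molarity: float,
                              ion_model: str = "solvated", seed: int = 0,
                              total_beads: int = 240, n_steps: int = 1500,
                              sample_every: int = 5, dt: float = 8.0,
                              temperature: float = 298.0,
                              pure_water_pad: float = 30.0,
                              wall_k: float = 20.0,
                              window: float = 0.5) -> obs.ObservableResult:
    """Walled-cell NVT osmotic pressure at one concentration (bar)."""
    conc = CompositionSpec(molarity, ion_model, total_beads)
    bundle = make_osmotic(conc, pure_water_pad=pure_water_pad, seed=seed,
                          wall_k=wall_k)
    ens = EnsembleSpec("NVT", temperature=temperature, dt=dt, seed=seed)
    sim = Simulation(bundle.frame, ff, ens, walls=bundle.walls,
                     topology=bundle.topology)
    sim.minimize(max_steps=50)
    sim.initialize_velocities()
    traj = sim.run(n_steps, sample_every)
    return obs.osmotic_pressure(traj, n_walls=len(bundle.walls), window=window)


PENALTY = 1e6  # objective value substituted for blown-up evaluations


def safe_protocol(fn, *args, **kwargs):
    """Run a protocol, mapping integration failures to None (the caller
    substitutes a large finite penalty so optimization can continue)."""
    try:
        return fn(*args, **kwargs)
    except (OverlapError, IntegrationBlowupError):
        return None
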