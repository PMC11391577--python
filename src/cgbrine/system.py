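"""In-memory containers for configurations, topologies and trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class Topology:
    """Bonded topology as index arrays plus per-entry force-field keys.

    ``bonds`` is an (n_bonds, 2) int array; ``bond_types`` the matching
    list of canonical type-pair keys.  ``angles`` is (n_angles, 3) with
    the apex bead in the middle.
    """

    type_names: list[str]  # per-bead type name, length N
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    bond_types: list[tuple[str, str]] = field(default_factory=list)
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=int))
    angle_types: list[tuple[str, str, str]] = field(default_factory=list)
    # per-bead molecule id (for COM-based observables and exclusions)
    molecule: np.ndarray | None = None

    def type_of(self, i: int) -> str:
        return self.type_names[i]

    @property
    def n_beads(self) -> int:
        return len(self.type_names)

    def exclusion_pairs(self) -> set[tuple[int, int]]:
        """1-2 and 1-3 pairs excluded from nonbonded interactions."""
        excl: set[tuple[int, int]] = set()
        for i, j in self.bonds:
            excl.add((min(i, j), max(i, j)))
        for i, j, k in self.angles:
            excl.add((min(i, k), max(i, k)))
        return excl


def empty_topology(type_names: Sequence[str]) -> Topology:
    return Topology(list(type_names))


@dataclass
class Frame:
    """One configuration: positions, velocities, box and time.

    The box is orthorhombic with origin at 0; positions are wrapped into
    the half-open cell [0, L) on output.
    """

    positions: np.ndarray  # (N, 3) Å
    velocities: np.ndarray  # (N, 3) Å/fs
    box: np.ndarray  # (3,) Å
    time: float = 0.0  # fs
    type_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if np.any(self.box <= 0):
            raise ValueError("all box lengths must be > 0")
        if self.velocities.shape != self.positions.shape:
            raise ValueError("positions and velocities must have the same shape")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def wrapped(self) -> "Frame":
        pos = self.positions - self.box * np.floor(self.positions / self.box)
        return Frame(pos, self.velocities.copy(), self.box.copy(), self.time,
                     list(self.type_names))

    def copy(self) -> "Frame":
        return Frame(self.positions.copy(), self.velocities.copy(),
                     self.box.copy(), self.time, list(self.type_names))


@dataclass
class Trajectory:
    """Ordered frames plus per-frame scalar channels (aligned by index)."""

    frames: list[Frame] = field(default_factory=list)
    sampling_interval: float = 0.0  # fs
    potential_energy: list[float] = field(default_factory=list)
    kinetic_energy: list[float] = field(default_factory=list)
    temperature: list[float] = field(default_factory=list)
    pressure_tensor: list[np.ndarray] = field(default_factory=list)  # (3,3) bar
    wall_forces: list[np.ndarray] = field(default_factory=list)  # per wall, kcal/mol/Å

    def append(self, frame: Frame, pe: float, ke: float, temp: float,
               ptens: np.ndarray, wall: np.ndarray) -> None:
        if self.frames and frame.time <= self.frames[-1].time:
            raise ValueError("frame times must be strictly increasing")
        self.frames.append(frame)
        self.potential_energy.append(pe)
        self.kinetic_energy.append(ke)
        self.temperature.append(temp)
        self.pressure_tensor.append(np.asarray(ptens, dtype=float))
        self.wall_forces.append(np.asarray(wall, dtype=float))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def boxes(self) -> np.ndarray:
        return np.array([f.box for f in self.frames])

    def window(self, fraction: float = 0.25) -> slice:
        """Index slice selecting the final ``fraction`` of the run
        (statistics window; the production-run convention is the last
        quarter of the trajectory)."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        start = int(round(len(self.frames) * (1.0 - fraction)))
        return slice(min(start, len(self.frames) - 1), len(self.frames))


@dataclass
class CompositionSpec:
    """Target composition of an aqueous NaCl system."""

    molarity: float  # mol/L
    ion_model: str = "solvated"  # or "bare"
    total_beads: int | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.molarity < 0:
            raise ValueError("molarity must be >= 0")
        if self.ion_model not in ("solvated", "bare"):
            raise ValueError("ion_model must be 'solvated' or 'bare'")


@dataclass
class SystemBundle:
    """A ready-to-run system: frame + topology + provenance + walls."""

    frame: Frame
    topology: Topology
    composition: CompositionSpec | None = None
    walls: list = field(default_factory=list)
    geometry: str = "bulk"  # bulk | slab | biphasic | osmotic | bilayer
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.topology.n_beads != self.frame.n_beads:
            raise ValueError("topology and frame disagree on bead count")
        if self.geometry == "osmotic" and not self.walls:
            raise ValueError("osmotic geometry requires walls")
        if self.geometry != "osmotic" and self.walls:
            raise ValueError(f"geometry {self.geometry!r} should not carry walls")
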