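"""File formats, run configuration and provenance manifests.

Formats
-------
* **data** — LAMMPS-style data file (``atom_style full`` columns:
  id mol type q x y z), Masses section with ``# name`` comments carrying
  the bead-type names, Bonds/Angles sections.  Orthorhombic box, origin
  at 0, half-open [0, L) wrapping.
* **dump** — LAMMPS-style text trajectory (``id type x y z [vx vy vz]``);
  readers re-sort by id.
* **internal** — ``.npz`` trajectory archive with every per-frame channel;
  round-trips bit-identically.
* **manifest** — JSON with config hash, seeds and per-file SHA-256
  checksums, sufficient to regenerate any artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .system import Frame, SystemBundle, Topology, Trajectory


class FileFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# dump trajectories
# ---------------------------------------------------------------------------

def write_dump(traj: Trajectory | list[Frame], path,
               with_velocities: bool = True) -> None:
    frames = traj.frames if isinstance(traj, Trajectory) else traj
    if not frames:
        raise ValueError("no frames to write")
    type_map = {t: i + 1 for i, t in enumerate(sorted(set(frames[0].type_names)))}
    with open(path, "w") as fh:
        for fi, f in enumerate(frames):
            fh.write("ITEM: TIMESTEP\n%d\n" % round(f.time))
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % f.n_beads)
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for ax in range(3):
                fh.write("0.0 %.10g\n" % f.box[ax])
            cols = ("id type element x y z"
                    + (" vx vy vz" if with_velocities else ""))
            fh.write(f"ITEM: ATOMS {cols}\n")
            for i in range(f.n_beads):
                row = "%d %d %s %.10g %.10g %.10g" % (
                    i + 1, type_map[f.type_names[i]], f.type_names[i],
                    *f.positions[i])
                if with_velocities:
                    row += " %.10g %.10g %.10g" % tuple(f.velocities[i])
                fh.write(row + "\n")


def read_dump(path) -> list[Frame]:
    """Parse a LAMMPS-style text dump; atoms re-sorted by id."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FileFormatError(f"{path}: empty dump file")
    lines = text.splitlines()
    frames: list[Frame] = []
    i = 0
    offset = 0
    frame_index = 0

    def fail(msg: str):
        raise FileFormatError(f"{path}: {msg} (near byte {offset}, "
                              f"frame {frame_index})")

    while i < len(lines):
        line = lines[i]
        if not line.strip() or line.startswith("#"):
            offset += len(line) + 1
            i += 1
            continue
        if not line.startswith("ITEM: TIMESTEP"):
            fail(f"expected ITEM: TIMESTEP, got {line!r}")
        try:
            t = float(lines[i + 1])
            n = int(lines[i + 3])
            box = np.array([float(lines[i + 5 + ax].split()[1]) for ax in range(3)])
            header = lines[i + 8]
            if not header.startswith("ITEM: ATOMS"):
                fail("missing ITEM: ATOMS header")
            cols = header.split()[2:]
            rows = lines[i + 9:i + 9 + n]
            if len(rows) < n:
                fail(f"truncated frame: expected {n} atom rows, got {len(rows)}")
            tokens = [r.split() for r in rows]
            ci = {c: k for k, c in enumerate(cols)}
            ids = np.array([int(tk[ci["id"]]) for tk in tokens])
            order = np.argsort(ids)
            tokens = [tokens[k] for k in order]
            pos = np.array([[float(tk[ci[c]]) for c in "xyz"] for tk in tokens])
            if {"vx", "vy", "vz"} <= set(cols):
                vel = np.array([[float(tk[ci[c]]) for c in ("vx", "vy", "vz")]
                                for tk in tokens])
            else:
                vel = np.zeros_like(pos)
            if "element" in ci:
                names = [tk[ci["element"]] for tk in tokens]
            else:
                names = [tk[ci["type"]] for tk in tokens]
        except (IndexError, ValueError) as exc:
            if isinstance(exc, FileFormatError):
                raise
            fail(f"malformed frame: {exc}")
        frames.append(Frame(pos, vel, box, t, names))
        consumed = lines[i:i + 9 + n]
        offset += sum(len(l) + 1 for l in consumed)
        i += 9 + n
        frame_index += 1
    if not frames:
        raise FileFormatError(f"{path}: no frames found")
    return frames


# ---------------------------------------------------------------------------
# data files (topology + one configuration)
# ---------------------------------------------------------------------------

def write_data(bundle: SystemBundle, path, masses: dict[str, float]) -> None:
    f = bundle.frame
    topo = bundle.topology
    types = sorted(set(f.type_names))
    tmap = {t: i + 1 for i, t in enumerate(types)}
    bond_keys = sorted(set(topo.bond_types))
    angle_keys = sorted(set(topo.angle_types))
    bmap = {k: i + 1 for i, k in enumerate(bond_keys)}
    amap = {k: i + 1 for i, k in enumerate(angle_keys)}
    charges = bundle.metadata.get("charges", {})
    mol = topo.molecule if topo.molecule is not None else np.full(f.n_beads, -1)
    with open(path, "w") as fh:
        fh.write("cgbrine data file\n\n")
        fh.write(f"{f.n_beads} atoms\n{len(topo.bonds)} bonds\n"
                 f"{len(topo.angles)} angles\n\n")
        fh.write(f"{len(types)} atom types\n{len(bond_keys)} bond types\n"
                 f"{len(angle_keys)} angle types\n\n")
        for ax, name in enumerate("xyz"):
            fh.write("0.0 %.10g %slo %shi\n" % (f.box[ax], name, name))
        fh.write("\nMasses\n\n")
        for t in types:
            fh.write("%d %.10g  # %s\n" % (tmap[t], masses[t], t))
        fh.write("\nAtoms  # full\n\n")
        for i in range(f.n_beads):
            fh.write("%d %d %d %.10g %.10g %.10g %.10g\n" % (
                i + 1, int(mol[i]) + 1, tmap[f.type_names[i]],
                charges.get(f.type_names[i], 0.0), *f.positions[i]))
        if len(topo.bonds):
            fh.write("\nBonds\n\n")
            for bi, ((i, j), key) in enumerate(zip(topo.bonds, topo.bond_types)):
                fh.write("%d %d %d %d\n" % (bi + 1, bmap[key], i + 1, j + 1))
        if len(topo.angles):
            fh.write("\nAngles\n\n")
            for ai, ((i, j, k), key) in enumerate(zip(topo.angles, topo.angle_types)):
                fh.write("%d %d %d %d %d\n" % (ai + 1, amap[key], i + 1, j + 1, k + 1))
        fh.write("\n# bond type map: "
                 + " ".join(f"{v}={k[0]}-{k[1]}" for k, v in bmap.items()) + "\n")
        fh.write("# angle type map: "
                 + " ".join(f"{v}={k[0]}-{k[1]}-{k[2]}" for k, v in amap.items())
                 + "\n")


def read_data(path) -> SystemBundle:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FileFormatError(f"{path}: empty data file")
    lines = text.splitlines()
    counts = {"atoms": 0, "bonds": 0, "angles": 0}
    box = np.zeros(3)
    type_names: dict[int, str] = {}
    bond_map: dict[int, tuple[str, str]] = {}
    angle_map: dict[int, tuple[str, str, str]] = {}
    for line in lines:
        s = line.strip()
        for key in counts:
            if s.endswith(f" {key}") and s.split()[0].isdigit():
                counts[key] = int(s.split()[0])
        for ax, name in enumerate("xyz"):
            if s.endswith(f"{name}lo {name}hi"):
                box[ax] = float(s.split()[1])
        if s.startswith("# bond type map:"):
            for tok in s.split(":", 1)[1].split():
                num, key = tok.split("=")
                bond_map[int(num)] = tuple(key.split("-"))  # type: ignore
        if s.startswith("# angle type map:"):
            for tok in s.split(":", 1)[1].split():
                num, key = tok.split("=")
                angle_map[int(num)] = tuple(key.split("-"))  # type: ignore

    def section(name: str) -> list[str]:
        out = []
        grab = False
        for line in lines:
            s = line.strip()
            if s.startswith(name):
                grab = True
                continue
            if grab:
                if not s:
                    if out:
                        break
                    continue
                if s[0].isalpha() or s.startswith("#"):
                    break
                out.append(s)
        return out

    for row in section("Masses"):
        parts = row.split("#")
        num = int(parts[0].split()[0])
        type_names[num] = parts[1].strip() if len(parts) > 1 else str(num)

    atoms = section("Atoms")
    if len(atoms) != counts["atoms"]:
        raise FileFormatError(f"{path}: expected {counts['atoms']} atom rows, "
                              f"found {len(atoms)}")
    n = counts["atoms"]
    pos = np.zeros((n, 3))
    names = [""] * n
    mol = np.zeros(n, dtype=int)
    for row in atoms:
        p = row.split()
        i = int(p[0]) - 1
        mol[i] = int(p[1]) - 1
        names[i] = type_names[int(p[2])]
        pos[i] = [float(p[4]), float(p[5]), float(p[6])]
    bonds, bond_types = [], []
    for row in section("Bonds"):
        p = row.split()
        bonds.append((int(p[2]) - 1, int(p[3]) - 1))
        bond_types.append(bond_map[int(p[1])])
    angles, angle_types = [], []
    for row in section("Angles"):
        p = row.split()
        angles.append((int(p[2]) - 1, int(p[3]) - 1, int(p[4]) - 1))
        angle_types.append(angle_map[int(p[1])])
    topo = Topology(names,
                    np.array(bonds, dtype=int) if bonds else np.zeros((0, 2), int),
                    bond_types,
                    np.array(angles, dtype=int) if angles else np.zeros((0, 3), int),
                    angle_types, molecule=mol)
    frame = Frame(pos, np.zeros((n, 3)), box, 0.0, names)
    return SystemBundle(frame, topo, geometry="bulk")


# ---------------------------------------------------------------------------
# internal trajectory format
# ---------------------------------------------------------------------------

def write_trajectory_npz(traj: Trajectory, path) -> None:
    np.savez(path,
             times=traj.times,
             boxes=traj.boxes,
             positions=np.array([f.positions for f in traj.frames]),
             velocities=np.array([f.velocities for f in traj.frames]),
             type_names=np.array(traj.frames[0].type_names),
             sampling_interval=np.array(traj.sampling_interval),
             potential_energy=np.array(traj.potential_energy),
             kinetic_energy=np.array(traj.kinetic_energy),
             temperature=np.array(traj.temperature),
             pressure_tensor=np.array(traj.pressure_tensor),
             wall_forces=np.array(traj.wall_forces),
             version=np.array("1"))


def read_trajectory_npz(path) -> Trajectory:
    try:
        z = np.load(path, allow_pickle=False)
    except Exception as exc:
        raise FileFormatError(f"{path}: unreadable trajectory archive: {exc}")
    if str(z["version"]) != "1":
        raise FileFormatError(f"{path}: unsupported trajectory version "
                              f"{z['version']}")
    names = [str(t) for t in z["type_names"]]
    traj = Trajectory(sampling_interval=float(z["sampling_interval"]))
    for k in range(len(z["times"])):
        traj.frames.append(Frame(z["positions"][k], z["velocities"][k],
                                 z["boxes"][k], float(z["times"][k]), names))
        traj.potential_energy.append(float(z["potential_energy"][k]))
        traj.kinetic_energy.append(float(z["kinetic_energy"][k]))
        traj.temperature.append(float(z["temperature"][k]))
        traj.pressure_tensor.append(z["pressure_tensor"][k])
        traj.wall_forces.append(z["wall_forces"][k])
    return traj


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA: dict[str, set[str]] = {
    "global": {"seed", "output_dir", "full_scale"},
    "system": {"geometry", "molarity", "ion_model", "total_beads", "seed",
               "min_dist", "n_lipids_per_leaflet", "oil", "n_oil", "n_aqueous",
               "pure_water_pad", "wall_k"},
    "engine": {"ensemble", "temperature", "pressure", "dt", "tau_t", "tau_p",
               "n_steps", "sample_every", "nonbonded", "seed", "minimize",
               "electrostatics"},
    "observables": {"window", "n_blocks", "which"},
    "fit": {"ion_model", "mode", "n_initial", "n_iterations", "acquisition",
            "seed", "concentrations", "w_density", "w_gamma", "total_beads",
            "n_steps", "bounds", "pi_target"},
}


@dataclass
class RunConfig:
    sections: dict[str, dict]

    def __post_init__(self) -> None:
        for name, content in self.sections.items():
            if name not in _CONFIG_SCHEMA:
                raise FileFormatError(f"unknown config section {name!r}")
            unknown = set(content) - _CONFIG_SCHEMA[name]
            if unknown:
                raise FileFormatError(
                    f"unknown keys in [{name}]: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise FileFormatError(f"{path}: config must be a mapping")
        return cls(data)

    def get(self, section: str, key: str, default=None):
        return self.sections.get(section, {}).get(key, default)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.sections, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seeds: list[int]
    version: str
    files: dict[str, str] = field(default_factory=dict)

    def add_file(self, path) -> None:
        self.files[str(Path(path).name)] = sha256_file(path)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "seeds": self.seeds,
                       "version": self.version, "files": self.files}, fh,
                      indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["config_hash"], d["seeds"], d["version"], d["files"])
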