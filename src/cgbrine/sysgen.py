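"""Synthetic-system and target-curve generation.

Everything the pipeline consumes is built here: packed bead
configurations of aqueous NaCl at 0–5 M in the five study geometries
(bulk box, z-tripled slab, oil/water biphasic stack, three-compartment
osmotic cell, toy bilayer), and concentration-resolved target curves for
density, surface tension and osmotic pressure.

Target curves come in three provenances:

* ``synthetic_parametric`` — smooth monotone stand-ins with the shape of
  the experimental data (documented coefficients, NOT measured values),
* ``ground_truth_sim`` — produced by the engine itself with a known
  parameter table, for recovery testing,
* ``user_table`` — read from CSV, for plugging in real measurements.

Packing is seeded rejection sampling with bounded retries (a PACKMOL
stand-in sufficient at CG bead densities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forcefield import (AngleSpec, BeadType, BondSpec, ElectrostaticsSpec,
                         ForceFieldTable, PairPotential)
from .system import CompositionSpec, Frame, SystemBundle, Topology
from .units import N_AVOGADRO, R_L_BAR, WATER_MOLARITY

WATERS_PER_BEAD = 3

#: toy amphiphile architecture — fixed here so head/tail selections for
#: APL, D_HH and order parameters are unambiguous everywhere
TOY_LIPID = {
    "beads": ["CHO", "PHO", "TAI", "TAI"],  # choline-like(+), phosphate-like(-), 2 tails
    "head_beads": ["CHO", "PHO"],
    "bond_r0": 4.0,  # Å
    "chain_bonds": [(1, 2), (2, 3)],  # bond positions used for order parameters
}


class PackingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# default force-field tables
# ---------------------------------------------------------------------------

def default_forcefield(ion_model: str = "solvated", *, waters_in_ion: int = 3,
                       electrostatics: ElectrostaticsSpec | None = None,
                       include_alkane: bool = False,
                       include_lipid: bool = False) -> ForceFieldTable:
    """A complete starting table for aqueous NaCl (+ optional toy species).

    Water follows the three-water CG bead convention (LJ 12-4,
    eps = 0.895 kcal/mol, sigma = 4.371 Å).  Ion parameters are starting
    values in a physically sensible range — they are what the fitting
    pipeline optimizes, not a published set.  Water-involving pairs use
    the 12-4 form, all others 9-6.
    """
    if ion_model not in ("solvated", "bare"):
        raise ValueError("ion_model must be 'solvated' or 'bare'")
    es = electrostatics or ElectrostaticsSpec()
    ff = ForceFieldTable(electrostatics=es)
    m_w = WATERS_PER_BEAD * 18.01528
    ff.add_bead(BeadType("W", m_w, 0.0, "water", WATERS_PER_BEAD))
    if ion_model == "solvated":
        ff.add_bead(BeadType("SOD", 22.9898 + waters_in_ion * 18.01528, +1.0,
                             "cation", waters_in_ion))
        ff.add_bead(BeadType("CLA", 35.4530 + waters_in_ion * 18.01528, -1.0,
                             "anion", waters_in_ion))
        sod_sig, cla_sig = 4.3, 4.5
        sod_eps, cla_eps = 0.80, 0.85
    else:
        ff.add_bead(BeadType("SOD", 22.9898, +1.0, "cation", 0))
        ff.add_bead(BeadType("CLA", 35.4530, -1.0, "anion", 0))
        sod_sig, cla_sig = 2.6, 3.6
        sod_eps, cla_eps = 0.35, 0.45
    ff.add_pair(PairPotential("W", "W", 0.895, 4.371, "lj12_4"))
    ff.add_pair(PairPotential("W", "SOD", 0.85, 0.5 * (4.371 + sod_sig), "lj12_4"))
    ff.add_pair(PairPotential("W", "CLA", 0.85, 0.5 * (4.371 + cla_sig), "lj12_4"))
    ff.add_pair(PairPotential("SOD", "SOD", sod_eps, sod_sig, "lj9_6"))
    ff.add_pair(PairPotential("CLA", "CLA", cla_eps, cla_sig, "lj9_6"))
    ff.add_pair(PairPotential("SOD", "CLA", math.sqrt(sod_eps * cla_eps),
                              0.5 * (sod_sig + cla_sig), "lj9_6"))
    if include_alkane or include_lipid:
        ff.add_bead(BeadType("CT", 42.081, 0.0, "alkane", 0))
        ff.add_pair(PairPotential("CT", "CT", 0.469, 4.506, "lj9_6"))
        ff.add_pair(PairPotential("W", "CT", 0.36, 4.44, "lj12_4"))
        for ion in ("SOD", "CLA"):
            p = ff.pair(ion, ion)
            ff.add_pair(PairPotential(ion, "CT", math.sqrt(p.epsilon * 0.469),
                                      0.5 * (p.sigma + 4.506), "lj9_6"))
        ff.bonded.add_bond(BondSpec("CT", "CT", 6.16, 3.65))
        ff.bonded.add_angle(AngleSpec("CT", "CT", "CT", 1.19, 173.0))
    if include_lipid:
        ff.add_bead(BeadType("CHO", 87.16, +1.0, "headgroup", 0))
        ff.add_bead(BeadType("PHO", 94.97, -1.0, "headgroup", 0))
        ff.add_bead(BeadType("TAI", 42.081, 0.0, "alkane", 0))
        heads = ["CHO", "PHO"]
        sig = {"CHO": 5.0, "PHO": 4.6, "TAI": 4.506}
        eps = {"CHO": 0.70, "PHO": 0.70, "TAI": 0.469}
        species = heads + ["TAI"]
        for i, a in enumerate(species):
            for b in species[i:]:
                ff.add_pair(PairPotential(a, b, math.sqrt(eps[a] * eps[b]),
                                          0.5 * (sig[a] + sig[b]), "lj9_6"))
            ff.add_pair(PairPotential("W", a,
                                      0.80 if a in heads else 0.36,
                                      0.5 * (4.371 + sig[a]), "lj12_4"))
            for ion in ("SOD", "CLA"):
                pi = ff.pair(ion, ion)
                ff.add_pair(PairPotential(ion, a, math.sqrt(pi.epsilon * eps[a]),
                                          0.5 * (pi.sigma + sig[a]), "lj9_6"))
            if include_alkane:
                ff.add_pair(PairPotential("CT", a, math.sqrt(0.469 * eps[a]),
                                          0.5 * (4.506 + sig[a]), "lj9_6"))
        ff.bonded.add_bond(BondSpec("CHO", "PHO", 6.16, 4.0))
        ff.bonded.add_bond(BondSpec("PHO", "TAI", 6.16, 4.0))
        ff.bonded.add_bond(BondSpec("TAI", "TAI", 6.16, 4.0))
        ff.bonded.add_angle(AngleSpec("CHO", "PHO", "TAI", 1.19, 160.0))
        ff.bonded.add_angle(AngleSpec("PHO", "TAI", "TAI", 1.19, 173.0))
    return ff


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

def pack_random(counts: dict[str, int], box, min_dist: float, seed: int,
                region: np.ndarray | None = None,
                existing: np.ndarray | None = None,
                max_tries: int = 2000) -> Frame:
    """Sequential rejection packing under periodic boundary conditions.

    All periodic pairwise distances (including against ``existing``
    coordinates) end up >= ``min_dist``.  ``region`` restricts insertion
    to a (3, 2) lo/hi sub-box.  Deterministic for a fixed seed.
    """
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    lo = np.zeros(3) if region is None else np.asarray(region, float)[:, 0]
    hi = box.copy() if region is None else np.asarray(region, float)[:, 1]
    n_total = int(sum(counts.values()))
    placed = np.zeros((n_total, 3))
    names: list[str] = []
    # spatial hash for O(1) neighbor checks
    cell = max(min_dist, 1e-6)
    ncell = np.maximum((box / cell).astype(int), 1)
    cell_size = box / ncell
    occupants: dict[tuple[int, int, int], list[int]] = {}
    ext = np.zeros((0, 3)) if existing is None else np.asarray(existing, float)
    all_pos = [ext[i] for i in range(len(ext))]
    for p in range(len(ext)):
        key = tuple((ext[p] // cell_size).astype(int) % ncell)
        occupants.setdefault(key, []).append(p)

    def ok(x: np.ndarray) -> bool:
        c = (x // cell_size).astype(int) % ncell
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    key = tuple((c + (dx, dy, dz)) % ncell)
                    for idx in occupants.get(key, ()):
                        d = all_pos[idx] - x
                        d -= box * np.round(d / box)
                        if float(d @ d) < min_dist * min_dist:
                            return False
        return True

    i = 0
    for name, cnt in counts.items():
        for _ in range(cnt):
            for attempt in range(max_tries):
                x = lo + rng.random(3) * (hi - lo)
                if ok(x):
                    break
            else:
                raise PackingError(
                    f"could not place bead {i} ({name}) after {max_tries} tries; "
                    "the requested density is infeasible for this min_dist — "
                    "use a larger box")
            placed[i] = x
            names.append(name)
            all_pos.append(x)
            key = tuple((x // cell_size).astype(int) % ncell)
            occupants.setdefault(key, []).append(len(all_pos) - 1)
            i += 1
    return Frame(placed, np.zeros((n_total, 3)), box, 0.0, names)


# ---------------------------------------------------------------------------
# composition bookkeeping
# ---------------------------------------------------------------------------

def counts_for_molarity(molarity: float, volume_A3: float, ion_model: str,
                        waters_in_ion: int = 3) -> tuple[int, int, int]:
    """(n_water_beads, n_cation, n_anion) for a box of given volume.

    Ion pairs: round(M·N_A·V).  Water molecules fill the remainder of
    the pure-water molar volume at 3 per bead, debiting the waters
    grouped into solvated ion beads.
    """
    if molarity < 0:
        raise ValueError("molarity must be >= 0")
    v_litre = volume_A3 * 1e-27
    n_pair = int(round(molarity * N_AVOGADRO * v_litre))
    n_water_molecules = int(round(WATER_MOLARITY * N_AVOGADRO * v_litre))
    if ion_model == "solvated":
        n_water_molecules -= 2 * n_pair * waters_in_ion
    if n_water_molecules < 0:
        raise ValueError(f"molarity {molarity} M leaves no free water in this box")
    n_water_beads = int(round(n_water_molecules / WATERS_PER_BEAD))
    return n_water_beads, n_pair, n_pair

def box_edge_for_total_beads(molarity: float, total_beads: int,
                             ion_model: str, waters_in_ion: int = 3) -> float:
    """Cubic box edge such that the composition holds ~total_beads beads."""
    beads_per_A3 = WATER_MOLARITY * N_AVOGADRO * 1e-27 / WATERS_PER_BEAD
    edge = (total_beads / beads_per_A3) ** (1.0 / 3.0)
    for _ in range(20):
        nw, nc, na = counts_for_molarity(molarity, edge**3, ion_model, waters_in_ion)
        tot = nw + nc + na
        if tot == 0:
            raise ValueError("empty system")
        edge *= (total_beads / tot) ** (1.0 / 3.0)
    return edge


def make_bulk(molarity: float, ion_model: str = "solvated",
              total_beads: int = 1100, seed: int = 0,
              min_dist: float = 3.4, waters_in_ion: int = 3) -> SystemBundle:
    """Cubic bulk solution; the default bead budget matches the
    1000–1200-bead bulk boxes of the study protocol."""
    edge = box_edge_for_total_beads(molarity, total_beads, ion_model, waters_in_ion)
    box = np.array([edge] * 3)
    nw, nc, na = counts_for_molarity(molarity, float(np.prod(box)), ion_model,
                                     waters_in_ion)
    frame = pack_random({"W": nw, "SOD": nc, "CLA": na}, box, min_dist, seed)
    comp = CompositionSpec(molarity, ion_model, nw + nc + na, box)
    return SystemBundle(frame, Topology(list(frame.type_names)), comp,
                        geometry="bulk")


# ---------------------------------------------------------------------------
# geometries
# ---------------------------------------------------------------------------

def make_slab(frame: Frame) -> Frame:
    """Triple the box along z, liquid slab centered, vacuum above/below."""
    new_box = frame.box.copy()
    new_box[2] *= 3.0
    pos = frame.positions.copy()
    pos[:, 2] = pos[:, 2] % frame.box[2] + frame.box[2]  # central third
    return Frame(pos, frame.velocities.copy(), new_box, frame.time,
                 list(frame.type_names))


def make_osmotic(conc: CompositionSpec, pure_water_pad: float = 30.0,
                 seed: int = 0, min_dist: float = 3.4,
                 wall_k: float = 20.0, waters_in_ion: int = 3,
                 force_law: str = "indent_quadratic") -> SystemBundle:
    """Three-compartment osmotic cell along x.

    Central concentrated compartment flanked by ion-free water pads; two
    one-sided virtual walls at the compartment boundaries act on ions
    only, water flows freely.  The default pad is twice the nonbonded
    cutoff so the pure phase has genuine bulk in the middle.
    """
    from .engine import WallSpec  # local import to avoid cycle
    if conc.molarity <= 0:
        raise ValueError("osmotic cell needs a nonzero ion concentration")
    if conc.box is not None:
        box_c = np.asarray(conc.box, dtype=float)
    else:
        edge = box_edge_for_total_beads(conc.molarity, conc.total_beads or 600,
                                        conc.ion_model, waters_in_ion)
        box_c = np.array([edge] * 3)
    nw, nc, na = counts_for_molarity(conc.molarity, float(np.prod(box_c)),
                                     conc.ion_model, waters_in_ion)
    lx_c = box_c[0]
    box = np.array([lx_c + 2.0 * pure_water_pad, box_c[1], box_c[2]])
    x_lo, x_hi = pure_water_pad, pure_water_pad + lx_c
    # central compartment
    frame = pack_random({"W": nw, "SOD": nc, "CLA": na}, box, min_dist, seed,
                        region=np.array([[x_lo, x_hi], [0, box[1]], [0, box[2]]]))
    # flanking pure water (one pad each side)
    pad_volume = pure_water_pad * box[1] * box[2]
    n_pad, _, _ = counts_for_molarity(0.0, pad_volume, "bare")
    for k, (lo, hi) in enumerate(((0.0, x_lo), (x_hi, box[0]))):
        pad = pack_random({"W": n_pad}, box, min_dist, seed + 1000 + k,
                          region=np.array([[lo, hi], [0, box[1]], [0, box[2]]]),
                          existing=frame.positions)
        frame = Frame(np.vstack([frame.positions, pad.positions]),
                      np.zeros((frame.n_beads + pad.n_beads, 3)), box, 0.0,
                      list(frame.type_names) + list(pad.type_names))
    walls = [WallSpec("x", x_lo, "-", wall_k, ("@cation", "@anion"), force_law),
             WallSpec("x", x_hi, "+", wall_k, ("@cation", "@anion"), force_law)]
    comp = CompositionSpec(conc.molarity, conc.ion_model, frame.n_beads, box)
    return SystemBundle(frame, Topology(list(frame.type_names)), comp,
                        walls=walls, geometry="osmotic",
                        metadata={"x_lo": x_lo, "x_hi": x_hi,
                                  "pad": pure_water_pad})


_OIL_CHAINS = {"decane_like": 3, "triolein_like": 5}


def make_biphasic(oil: str, n_oil: int, n_aqueous: int,
                  conc: CompositionSpec, seed: int = 0,
                  min_dist: float = 3.4, waters_in_ion: int = 3) -> SystemBundle:
    """Oil slab stacked on an aqueous slab along z.

    Oil molecules are short LJ-bead chains (3 beads for the decane-like
    species, 5 for the triolein-like one) with bonds and angles from the
    bonded table.  Desk-scale counts are ~10× below the full-size study
    systems.
    """
    if oil not in _OIL_CHAINS:
        raise ValueError(f"unknown oil {oil!r}")
    if n_oil < 1 or n_aqueous < 1:
        raise ValueError("counts must be >= 1")
    chain_len = _OIL_CHAINS[oil]
    # lateral box from aqueous bead budget at water-like density
    beads_per_A3 = WATER_MOLARITY * N_AVOGADRO * 1e-27 / WATERS_PER_BEAD
    v_aq = n_aqueous / beads_per_A3
    lxy = v_aq ** (1.0 / 3.0)
    lz_aq = v_aq / lxy**2
    oil_density = 0.0045  # beads/Å³, alkane-like
    lz_oil = n_oil * chain_len / oil_density / lxy**2
    box = np.array([lxy, lxy, lz_aq + lz_oil])
    # aqueous phase in [0, lz_aq)
    nw, nc, na = counts_for_molarity(conc.molarity, v_aq, conc.ion_model,
                                     waters_in_ion)
    n_extra = n_aqueous - (nw + nc + na)
    nw = max(nw + n_extra, 0)
    frame = pack_random({"W": nw, "SOD": nc, "CLA": na}, box, min_dist, seed,
                        region=np.array([[0, box[0]], [0, box[1]],
                                         [0.0, lz_aq]]))
    # oil chains on a grid in [lz_aq, lz)
    bond_r0 = 3.65
    per_row = max(int(lxy // 4.5), 1)
    positions = [frame.positions]
    names = list(frame.type_names)
    bonds, bond_types, angles, angle_types, mol = [], [], [], [], []
    mol += [-1] * frame.n_beads
    idx = frame.n_beads
    rng = np.random.default_rng(seed + 7)
    for m in range(n_oil):
        gx = (m % per_row + 0.5) * lxy / per_row
        gy = ((m // per_row) % per_row + 0.5) * lxy / per_row
        layer = m // (per_row * per_row)
        gz = lz_aq + 2.5 + layer * (chain_len * bond_r0 * 0.6 + 3.0)
        base = np.array([gx, gy, gz]) + rng.normal(scale=0.1, size=3)
        for b in range(chain_len):
            positions.append((base + [0.3 * rng.normal(), 0.3 * rng.normal(),
                                      b * bond_r0 * 0.95])[None, :])
            names.append("CT")
            mol.append(m)
            if b > 0:
                bonds.append((idx - 1, idx))
                bond_types.append(("CT", "CT"))
            if b > 1:
                angles.append((idx - 2, idx - 1, idx))
                angle_types.append(("CT", "CT", "CT"))
            idx += 1
    all_pos = np.vstack(positions)
    frame = Frame(all_pos, np.zeros((len(all_pos), 3)), box, 0.0, names)
    topo = Topology(names, np.array(bonds if bonds else np.zeros((0, 2)), dtype=int),
                    bond_types,
                    np.array(angles if angles else np.zeros((0, 3)), dtype=int),
                    angle_types, molecule=np.array(mol))
    comp = CompositionSpec(conc.molarity, conc.ion_model, len(all_pos), box)
    return SystemBundle(frame, topo, comp, geometry="biphasic",
                        metadata={"oil": oil, "lz_aqueous": lz_aq})


def make_toy_bilayer(n_lipids_per_leaflet: int, conc: CompositionSpec,
                     seed: int = 0, apl0: float = 60.0,
                     min_dist: float = 3.4, waters_in_ion: int = 3,
                     water_pad: float = 25.0) -> SystemBundle:
    """Two leaflets of 4-bead amphiphiles spanning xy, solvated with
    water + ions above and below.

    Architecture is fixed by :data:`TOY_LIPID`: a choline-like (+1) and
    phosphate-like (-1) head bead over two apolar tail beads; head beads
    are the D_HH / density-profile selection, tail bonds the
    order-parameter chain.
    """
    n = n_lipids_per_leaflet
    if n < 4:
        raise ValueError("need at least 4 lipids per leaflet")
    side = int(math.ceil(math.sqrt(n)))
    lxy = math.sqrt(n * apl0)
    spacing = lxy / side
    beads = TOY_LIPID["beads"]
    dz = TOY_LIPID["bond_r0"]
    n_bead_lipid = len(beads)
    half_thick = n_bead_lipid * dz  # head out at mid + half_thick
    lz = 2.0 * (half_thick + water_pad)
    box = np.array([lxy, lxy, lz])
    mid = lz / 2.0
    positions, names, mol = [], [], []
    bonds, bond_types, angles, angle_types = [], [], [], []
    rng = np.random.default_rng(seed)
    idx = 0
    for leaflet, sign in ((0, +1), (1, -1)):
        for m in range(n):
            gx = (m % side + 0.5) * spacing
            gy = ((m // side) % side + 0.5) * spacing
            jitter = rng.normal(scale=0.2, size=2)
            # bead 0 (outermost head) ... bead L-1 (innermost tail)
            start = idx
            for b, bead in enumerate(beads):
                z = mid + sign * (half_thick - b * dz)
                positions.append([gx + jitter[0], gy + jitter[1], z])
                names.append(bead)
                mol.append(leaflet * n + m)
                if b > 0:
                    bonds.append((idx - 1, idx))
                    bond_types.append((beads[b - 1], bead))
                if b > 1:
                    angles.append((idx - 2, idx - 1, idx))
                    angle_types.append((beads[b - 2], beads[b - 1], bead))
                idx += 1
    pos = np.array(positions)
    # solvate: water+ions in the two slabs outside the membrane
    v_water = lxy * lxy * (lz - 2.0 * half_thick - 4.0)
    nw, nc, na = counts_for_molarity(conc.molarity, v_water, conc.ion_model,
                                     waters_in_ion)
    lo_top, hi_top = mid + half_thick + 2.0, lz
    lo_bot, hi_bot = 0.0, mid - half_thick - 2.0
    half_counts = {"W": nw // 2, "SOD": nc // 2, "CLA": na // 2}
    rest_counts = {"W": nw - nw // 2, "SOD": nc - nc // 2, "CLA": na - na // 2}
    top = pack_random(half_counts, box, min_dist, seed + 11,
                      region=np.array([[0, lxy], [0, lxy], [lo_top, hi_top]]),
                      existing=pos)
    bot = pack_random(rest_counts, box, min_dist, seed + 12,
                      region=np.array([[0, lxy], [0, lxy], [lo_bot, hi_bot]]),
                      existing=np.vstack([pos, top.positions]))
    # enforce electroneutrality after the integer split (counts are equal
    # already: nc == na)
    all_pos = np.vstack([pos, top.positions, bot.positions])
    all_names = names + list(top.type_names) + list(bot.type_names)
    mol += [-1] * (top.n_beads + bot.n_beads)
    frame = Frame(all_pos, np.zeros((len(all_pos), 3)), box, 0.0, all_names)
    topo = Topology(all_names, np.array(bonds, dtype=int), bond_types,
                    np.array(angles, dtype=int), angle_types,
                    molecule=np.array(mol))
    comp = CompositionSpec(conc.molarity, conc.ion_model, len(all_pos), box)
    meta = {"n_lipids_per_leaflet": n, "midplane": mid,
            "head_beads": TOY_LIPID["head_beads"],
            "beads_per_lipid": n_bead_lipid}
    return SystemBundle(frame, topo, comp, geometry="bilayer", metadata=meta)


def head_indices(bundle: SystemBundle) -> np.ndarray:
    """Bead indices of the bilayer head beads (D_HH / profile selection)."""
    heads = set(bundle.metadata.get("head_beads", TOY_LIPID["head_beads"]))
    return np.array([i for i, t in enumerate(bundle.frame.type_names)
                     if t in heads], dtype=int)


def chain_definitions(bundle: SystemBundle) -> np.ndarray:
    """(n_lipids, n_bonds, 2) bead-index array of the tail bonds used for
    order parameters, derived from the fixed toy-lipid architecture."""
    n_per = bundle.metadata.get("beads_per_lipid", len(TOY_LIPID["beads"]))
    mol = bundle.topology.molecule
    if mol is None:
        raise ValueError("bundle topology carries no molecule ids")
    lipids = sorted({m for m in mol if m >= 0})
    first = {m: int(np.argmax(mol == m)) for m in lipids}
    bonds = TOY_LIPID["chain_bonds"]
    return np.array([[[first[m] + a, first[m] + b] for a, b in bonds]
                     for m in lipids], dtype=int)


# ---------------------------------------------------------------------------
# target curves
# ---------------------------------------------------------------------------

@dataclass
class TargetCurve:
    """Concentration-indexed property values with uncertainties."""

    property: str  # density | surface_tension | osmotic_pressure | interfacial_tension
    molarities: np.ndarray  # mol/L, strictly increasing
    values: np.ndarray
    uncertainties: np.ndarray
    units: str
    provenance: str  # synthetic_parametric | ground_truth_sim | user_table

    def __post_init__(self) -> None:
        self.molarities = np.asarray(self.molarities, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.uncertainties = np.asarray(self.uncertainties, dtype=float)
        if np.any(np.diff(self.molarities) <= 0):
            raise ValueError("molarities must be strictly increasing")
        if np.any(self.uncertainties <= 0):
            raise ValueError("uncertainties must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"molarity": self.molarities, "value": self.values,
                             "uncertainty": self.uncertainties,
                             "units": self.units, "provenance": self.provenance})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, property: str) -> "TargetCurve":
        df = pd.read_csv(path)
        return cls(property, df["molarity"].to_numpy(), df["value"].to_numpy(),
                   df["uncertainty"].to_numpy(), str(df["units"].iloc[0]),
                   "user_table")

    def value_at(self, molarity: float) -> float:
        return float(np.interp(molarity, self.molarities, self.values))


#: synthetic stand-in coefficients (shape-matched to real NaCl data,
#: documented as stand-ins — see docs/methods.md)
DENSITY_RHO0 = 998.0  # kg/m³ at ~0 M
DENSITY_SLOPE = 38.0  # kg/m³ per mol/L
TENSION_GAMMA0 = 72.8  # mN/m
TENSION_SLOPE = 1.64  # mN/m per mol/L
OSMOTIC_PHI = (0.92, 0.02, 0.004)  # phi(c) = a + b c + c2 c², monotone


def osmotic_coefficient(molarity) -> np.ndarray:
    a, b, c2 = OSMOTIC_PHI
    c = np.asarray(molarity, dtype=float)
    return a + b * c + c2 * c * c


DEFAULT_CONCENTRATIONS = np.arange(0.5, 5.01, 0.5)


def reference_targets(property: str, mode: str = "synthetic_parametric",
                      seed: int = 0,
                      concentrations: np.ndarray | None = None,
                      noise: float = 0.0, temperature: float = 298.0,
                      ground_truth: dict | None = None,
                      ideal_osmotic: bool = False) -> TargetCurve:
    """Concentration-resolved target curve for one property.

    ``synthetic_parametric`` curves use the documented stand-in
    coefficients; ``noise`` adds seeded Gaussian scatter (in the curve's
    units).  ``ground_truth_sim`` runs the engine with a known parameter
    table (passed via ``ground_truth``; see
    :func:`simulate_ground_truth_targets`).
    """
    if mode not in ("synthetic_parametric", "ground_truth_sim"):
        raise ValueError(f"unknown mode {mode!r}")
    conc = np.asarray(concentrations if concentrations is not None
                      else DEFAULT_CONCENTRATIONS, dtype=float)
    if mode == "ground_truth_sim":
        gt = dict(ground_truth or {})
        return simulate_ground_truth_targets(property, conc, seed=seed, **gt)
    rng = np.random.default_rng(seed)
    if property == "density":
        vals = DENSITY_RHO0 + DENSITY_SLOPE * conc
        unc, units = 1.0, "kg/m^3"
    elif property in ("surface_tension", "interfacial_tension"):
        vals = TENSION_GAMMA0 + TENSION_SLOPE * conc
        unc, units = 1.0, "mN/m"
    elif property == "osmotic_pressure":
        phi = 1.0 if ideal_osmotic else osmotic_coefficient(conc)
        vals = 2.0 * conc * R_L_BAR * temperature * phi
        unc, units = None, "bar"
    else:
        raise ValueError(f"unknown property {property!r}")
    if noise > 0:
        vals = vals + rng.normal(scale=noise, size=vals.shape)
    if unc is None:
        unc_arr = np.maximum(0.05 * np.abs(vals), 0.1)
    else:
        unc_arr = np.full_like(vals, max(unc, noise if noise > 0 else unc))
    return TargetCurve(property, conc, vals, unc_arr, units,
                       "synthetic_parametric")


def simulate_ground_truth_targets(property: str, concentrations: np.ndarray,
                                  ff: ForceFieldTable | None = None,
                                  ion_model: str = "solvated",
                                  seed: int = 0, total_beads: int = 150,
                                  n_steps: int = 600, sample_every: int = 5,
                                  dt: float = 8.0,
                                  temperature: float = 293.0) -> TargetCurve:
    """Engine-generated targets with a known table (recovery testing).

    Runs the same reduced protocol the condition-1 objective uses, so an
    optimization evaluated with identical seeds reproduces these values
    exactly at the true parameters.
    """
    from .protocols import simulate_density, simulate_surface_tension
    if ff is None:
        ff = default_forcefield(ion_model,
                                electrostatics=ElectrostaticsSpec(
                                    method="cutoff_shifted"))
    vals, uncs = [], []
    conc_sorted = np.sort(np.asarray(concentrations, dtype=float))
    for i, c in enumerate(conc_sorted):
        # seed + concentration-index convention shared with the condition-1
        # objective, so identical protocols reproduce these values exactly
        if property == "density":
            res = simulate_density(ff, c, ion_model=ion_model, seed=seed + i,
                                   total_beads=total_beads, n_steps=n_steps,
                                   sample_every=sample_every, dt=dt,
                                   temperature=temperature)
            units = "kg/m^3"
        elif property == "surface_tension":
            res = simulate_surface_tension(ff, c, ion_model=ion_model, seed=seed + i,
                                           total_beads=total_beads,
                                           n_steps=n_steps,
                                           sample_every=sample_every, dt=dt,
                                           temperature=temperature)
            units = "mN/m"
        else:
            raise ValueError(f"ground_truth_sim supports density and "
                             f"surface_tension, not {property!r}")
        vals.append(res.value)
        uncs.append(max(res.uncertainty, 1e-9))
    return TargetCurve(property, conc_sorted, np.array(vals), np.array(uncs),
                       units, "ground_truth_sim")
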