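"""Trajectory estimators: density, Kirkwood–Irving tensions, osmotic
pressure, bilayer metrics, order parameters, density profiles.

All estimators operate on a statistics window (default: the final 25 %
of the trajectory, the last-quarter-of-production convention) and report
block-averaged standard errors over 5 contiguous blocks.

Unit conventions at this boundary: densities in kg/m³, tensions in
mN/m, pressures in bar, lengths in Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .system import Trajectory
from .units import AMU_A3_TO_KG_M3, BAR_A_TO_MN_M


@dataclass
class ObservableResult:
    value: float
    uncertainty: float  # block-average standard error, same units
    window: float  # analyzed time span, fs
    n_blocks: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


@dataclass
class BilayerMetrics:
    apl: ObservableResult  # Å²
    d_hh: ObservableResult  # Å
    order: dict[int, ObservableResult]  # keyed by bond position along the chain

    def __post_init__(self) -> None:
        if self.apl.value <= 0 or self.d_hh.value <= 0:
            raise ValueError("apl and d_hh must be > 0")
        for pos, s in self.order.items():
            if not (-0.5 - 1e-9 <= s.value <= 1.0 + 1e-9):
                raise ValueError(f"order parameter at bond {pos} out of [-0.5, 1]")


# ---------------------------------------------------------------------------
# block statistics
# ---------------------------------------------------------------------------

def block_error(series, n_blocks: int = 5) -> float:
    """Standard error of contiguous block means (trailing remainder kept
    in the last block)."""
    x = np.asarray(series, dtype=float)
    if len(x) < n_blocks:
        raise ValueError(f"series of length {len(x)} too short for "
                         f"{n_blocks} blocks")
    means = [b.mean() for b in np.array_split(x, n_blocks)]
    return float(np.std(means, ddof=1) / math.sqrt(n_blocks))


def _block_stats(series, n_blocks: int = 5) -> tuple[float, float]:
    x = np.asarray(series, dtype=float)
    if len(x) == 0:
        raise ValueError("empty statistics window")
    if len(x) < n_blocks:
        return float(x.mean()), 0.0
    return float(x.mean()), block_error(x, n_blocks)


def _window_span(traj: Trajectory, sl: slice) -> float:
    t = traj.times[sl]
    return float(t[-1] - t[0]) if len(t) > 1 else 0.0


# ---------------------------------------------------------------------------
# scalar thermodynamic estimators
# ---------------------------------------------------------------------------

def mass_density(traj: Trajectory, masses: np.ndarray,
                 window: float = 0.25, n_blocks: int = 5) -> ObservableResult:
    """⟨Σm⟩/⟨V⟩ over the window, in kg/m³ (masses per bead, amu)."""
    sl = traj.window(window)
    total_mass = float(np.sum(masses))
    vols = np.array([f.volume for f in traj.frames[sl]])
    rho = total_mass / vols * AMU_A3_TO_KG_M3
    value, err = _block_stats(rho, n_blocks)
    return ObservableResult(value, err, _window_span(traj, sl), n_blocks)


def _anisotropy(traj: Trajectory, sl: slice, axis: int) -> np.ndarray:
    """P_N - (P_T1 + P_T2)/2 per frame, bar."""
    out = []
    for p in traj.pressure_tensor[sl]:
        trans = [a for a in range(3) if a != axis]
        out.append(p[axis, axis] - 0.5 * (p[trans[0], trans[0]]
                                          + p[trans[1], trans[1]]))
    return np.array(out)


def _slab_warning(traj: Trajectory, sl: slice, axis: int) -> list[str]:
    # a slab should leave vacuum: bead extent along the axis well short of L
    f = traj.frames[sl.start]
    coords = f.positions[:, axis]
    if len(coords) == 0:
        return ["empty frame"]
    extent = coords.max() - coords.min()
    if extent > 0.95 * f.box[axis]:
        return ["trajectory does not look like a slab along the requested "
                "axis (no vacuum gap); the tension estimator assumes two "
                "interfaces"]
    return []


def surface_tension(traj: Trajectory, normal_axis: str = "z",
                    window: float = 0.25, n_blocks: int = 5) -> ObservableResult:
    """Kirkwood–Irving surface tension of a two-interface slab:
    γ = (L_N/2)·⟨P_N − (P_T1+P_T2)/2⟩, reported in mN/m.  The ½ accounts
    for the two liquid–vapor interfaces; the box is fixed (NVT)."""
    ax = "xyz".index(normal_axis)
    sl = traj.window(window)
    dp = _anisotropy(traj, sl, ax)
    lz = np.array([f.box[ax] for f in traj.frames[sl]])
    gamma = 0.5 * lz * dp * BAR_A_TO_MN_M
    value, err = _block_stats(gamma, n_blocks)
    return ObservableResult(value, err, _window_span(traj, sl), n_blocks,
                            warnings=_slab_warning(traj, sl, ax))


def interfacial_tension(traj: Trajectory, normal_axis: str = "z",
                        window: float = 0.25, n_blocks: int = 5) -> ObservableResult:
    """Same estimator for a biphasic NPzAT run, with ⟨L_N⟩ replacing the
    fixed box length (the normal axis fluctuates under the barostat)."""
    ax = "xyz".index(normal_axis)
    sl = traj.window(window)
    dp = _anisotropy(traj, sl, ax)
    lz = np.array([f.box[ax] for f in traj.frames[sl]])
    mean_lz = float(lz.mean())
    per_frame = 0.5 * mean_lz * dp * BAR_A_TO_MN_M
    value, err = _block_stats(per_frame, n_blocks)
    return ObservableResult(value, err, _window_span(traj, sl), n_blocks)


def osmotic_pressure(traj: Trajectory, n_walls: int = 2,
                     window: float = 0.25, n_blocks: int = 5,
                     area_axes: tuple[int, int] = (1, 2)) -> ObservableResult:
    """Osmotic pressure from the semipermeable-wall force channels:
    Π = ⟨F_wall⟩/(L_y·L_z) per wall, averaged over walls, in bar."""
    sl = traj.window(window)
    wf = np.array(traj.wall_forces[sl])
    if wf.ndim != 2 or wf.shape[1] < n_walls:
        raise ValueError("trajectory carries no wall-force channels for "
                         f"{n_walls} walls")
    from .units import KCAL_MOL_A3_TO_BAR
    areas = np.array([f.box[area_axes[0]] * f.box[area_axes[1]]
                      for f in traj.frames[sl]])
    pi_frames = wf[:, :n_walls].mean(axis=1) / areas * KCAL_MOL_A3_TO_BAR
    value, err = _block_stats(pi_frames, n_blocks)
    return ObservableResult(value, err, _window_span(traj, sl), n_blocks)


# ---------------------------------------------------------------------------
# bilayer metrics
# ---------------------------------------------------------------------------

def area_per_lipid(traj: Trajectory, n_lipids_per_leaflet: int,
                   window: float = 0.25, n_blocks: int = 5) -> ObservableResult:
    """APL = ⟨L_x⟩·⟨L_y⟩ / N_lpl in Å²."""
    if n_lipids_per_leaflet <= 0:
        raise ValueError("n_lipids_per_leaflet must be > 0")
    sl = traj.window(window)
    areas = np.array([f.box[0] * f.box[1] for f in traj.frames[sl]])
    per_frame = areas / n_lipids_per_leaflet
    value, err = _block_stats(per_frame, n_blocks)
    return ObservableResult(value, err, _window_span(traj, sl), n_blocks)


def headgroup_distance(traj: Trajectory, head_selection: np.ndarray,
                       masses: np.ndarray | None = None,
                       window: float = 0.25, n_blocks: int = 5) -> ObservableResult:
    """D_HH: |z-COM of upper-leaflet heads − z-COM of lower-leaflet heads|.

    ``head_selection`` holds bead indices of the head beads; leaflet
    membership is assigned by the sign of z relative to the head COM at
    the window start and kept fixed (flip-flop is not tracked)."""
    head_selection = np.asarray(head_selection, dtype=int)
    if head_selection.size == 0:
        raise ValueError("empty head selection")
    sl = traj.window(window)
    w = (np.ones(head_selection.size) if masses is None
         else np.asarray(masses, dtype=float)[head_selection])
    z0 = traj.frames[sl.start].positions[head_selection, 2]
    mid = float(np.average(z0, weights=w))
    upper = head_selection[z0 >= mid]
    lower = head_selection[z0 < mid]
    if len(upper) == 0 or len(lower) == 0:
        raise ValueError("could not split heads into two leaflets")
    wu = np.ones(len(upper)) if masses is None else np.asarray(masses)[upper]
    wl = np.ones(len(lower)) if masses is None else np.asarray(masses)[lower]
    d = []
    for f in traj.frames[sl]:
        zu = float(np.average(f.positions[upper, 2], weights=wu))
        zl = float(np.average(f.positions[lower, 2], weights=wl))
        d.append(abs(zu - zl))
    value, err = _block_stats(np.array(d), n_blocks)
    return ObservableResult(value, err, _window_span(traj, sl), n_blocks)


def order_parameters(traj: Trajectory, chain_definitions,
                     normal: str = "z", window: float = 0.25,
                     n_blocks: int = 5) -> dict[int, ObservableResult]:
    """Bond order parameter S = ½(3⟨(b̂·n̂)²⟩ − 1) per bond position.

    ``chain_definitions`` is an (n_chains, n_bonds, 2) index array of
    consecutive bead pairs along each chain; averaging runs over chains
    and frames.  Zero-length bond vectors are excluded with a warning
    entry on the affected position.
    """
    chains = np.asarray(chain_definitions, dtype=int)
    if chains.ndim != 3 or chains.shape[2] != 2:
        raise ValueError("chain_definitions must have shape (n_chains, n_bonds, 2)")
    ax = "xyz".index(normal)
    sl = traj.window(window)
    n_bonds = chains.shape[1]
    per_pos_series: list[list[float]] = [[] for _ in range(n_bonds)]
    warn_pos: set[int] = set()
    for f in traj.frames[sl]:
        for pos in range(n_bonds):
            i = chains[:, pos, 0]
            j = chains[:, pos, 1]
            b = f.positions[j] - f.positions[i]
            b -= f.box * np.round(b / f.box)
            norm = np.linalg.norm(b, axis=1)
            good = norm > 1e-10
            if not np.all(good):
                warn_pos.add(pos)
            if not np.any(good):
                continue
            cos2 = (b[good, ax] / norm[good]) ** 2
            per_pos_series[pos].append(float(np.mean(1.5 * cos2 - 0.5)))
    out: dict[int, ObservableResult] = {}
    for pos in range(n_bonds):
        series = np.array(per_pos_series[pos])
        value, err = _block_stats(series, n_blocks)
        warns = (["zero-length bond vectors excluded"] if pos in warn_pos else [])
        out[pos] = ObservableResult(value, err, _window_span(traj, sl),
                                    n_blocks, warnings=warns)
    return out


def bilayer_metrics(traj: Trajectory, n_lipids_per_leaflet: int,
                    head_selection: np.ndarray, chain_definitions,
                    masses: np.ndarray | None = None,
                    window: float = 0.25, n_blocks: int = 5) -> BilayerMetrics:
    """APL, D_HH and per-bond order parameters in one pass."""
    return BilayerMetrics(
        apl=area_per_lipid(traj, n_lipids_per_leaflet, window, n_blocks),
        d_hh=headgroup_distance(traj, head_selection, masses, window, n_blocks),
        order=order_parameters(traj, chain_definitions, window=window,
                               n_blocks=n_blocks))


def density_profile(traj: Trajectory, axis: str, selection: np.ndarray,
                    bin_width: float, window: float = 0.25,
                    center_on: np.ndarray | None = None):
    """Number-density histogram along an axis, per-frame and per-bin-volume
    normalized (counts/Å³).  ``center_on`` optionally recenters each frame
    on the mean coordinate of that selection (e.g. the bilayer midplane).

    Returns (bin_centers, density) arrays.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    selection = np.asarray(selection, dtype=int)
    ax = "xyz".index(axis)
    sl = traj.window(window)
    frames = traj.frames[sl]
    L = float(frames[0].box[ax])
    nbins = max(int(round(L / bin_width)), 1)
    edges = np.linspace(0.0, L, nbins + 1)
    counts = np.zeros(nbins)
    for f in frames:
        x = f.positions[:, ax].copy()
        if center_on is not None and len(center_on):
            shift = float(np.mean(f.positions[np.asarray(center_on, int), ax])) - L / 2
            x = (x - shift) % L
        if selection.size:
            h, _ = np.histogram(x[selection] % L, bins=edges)
            counts += h
    others = [a for a in range(3) if a != ax]
    bin_volume = (edges[1] - edges[0]) * float(frames[0].box[others[0]]
                                               * frames[0].box[others[1]])
    density = counts / (len(frames) * bin_volume)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density
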