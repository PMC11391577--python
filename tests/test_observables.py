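"""Estimator unit tests on hand-built synthetic trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgbrine import Frame, Trajectory
from cgbrine import observables as obs
from cgbrine.units import AMU_A3_TO_KG_M3


def synthetic_traj(n_frames, box, positions=None, n=8, ptens=None,
                   wall=None, names=None, jitter=0.0, seed=0):
    """Trajectory of identical (or jittered) frames with prescribed
    per-frame pressure tensors / wall forces."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    if positions is None:
        positions = rng.random((n, 3)) * box
    names = names or ["A"] * len(positions)
    traj = Trajectory(sampling_interval=100.0)
    for k in range(n_frames):
        pos = positions + (rng.normal(scale=jitter, size=positions.shape)
                           if jitter else 0.0)
        p = (ptens[k] if ptens is not None else np.zeros((3, 3)))
        w = (wall[k] if wall is not None else np.zeros(2))
        f = Frame(pos % box, np.zeros_like(positions), box.copy(),
                  100.0 * (k + 1), list(names))
        traj.append(f, 0.0, 0.0, 0.0, p, w)
    return traj


class TestDensity:
    def test_hand_unit_conversion(self):
        # 1000 beads × 100 amu in (50 Å)³ -> 1328.4 kg/m³
        traj = synthetic_traj(8, [50.0] * 3, n=1000)
        r = obs.mass_density(traj, np.full(1000, 100.0), window=1.0)
        assert r.value == pytest.approx(0.8 * AMU_A3_TO_KG_M3, rel=1e-12)
        assert r.value == pytest.approx(1328.4, abs=0.1)

    def test_linearity_in_mass_and_zero_uncertainty_static(self):
        traj = synthetic_traj(10, [40.0] * 3, n=100)
        r1 = obs.mass_density(traj, np.full(100, 50.0), window=1.0)
        r2 = obs.mass_density(traj, np.full(100, 100.0), window=1.0)
        assert r2.value == pytest.approx(2 * r1.value, rel=1e-12)
        assert r1.uncertainty == 0.0


class TestKirkwoodIrving:
    def test_isotropic_pressure_gives_zero(self):
        ptens = [np.eye(3) * 250.0 for _ in range(10)]
        traj = synthetic_traj(10, [40, 40, 120], ptens=np.array(ptens))
        r = obs.surface_tension(traj, window=1.0)
        assert r.value == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_100bar_anisotropy_over_100A(self):
        # P_zz - (P_xx+P_yy)/2 = 100 bar, L_z = 100 Å -> γ = 50 mN/m
        p = np.diag([100.0, 100.0, 200.0])
        positions = np.random.default_rng(0).random((8, 3)) * [40, 40, 50]
        traj = synthetic_traj(10, [40, 40, 100], positions=positions,
                              ptens=np.array([p] * 10))
        r = obs.surface_tension(traj, window=1.0)
        assert r.value == pytest.approx(50.0, rel=1e-12)
        assert not r.warnings  # particles occupy half the box: slab-like

    def test_transverse_axis_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(10):
            pxx, pyy, pzz = rng.normal(100, 20, 3)
            ps.append(np.diag([pxx, pyy, pzz]))
        positions = rng.random((8, 3)) * [40, 40, 50]
        t1 = synthetic_traj(10, [40, 40, 100], positions=positions,
                            ptens=np.array(ps))
        swapped = [np.diag([p[1, 1], p[0, 0], p[2, 2]]) for p in ps]
        t2 = synthetic_traj(10, [40, 40, 100], positions=positions,
                            ptens=np.array(swapped))
        a = obs.surface_tension(t1, window=1.0)
        b = obs.surface_tension(t2, window=1.0)
        assert a.value == pytest.approx(b.value, rel=1e-12)

    def test_non_slab_geometry_attaches_warning(self):
        traj = synthetic_traj(6, [40, 40, 40], n=200, seed=3)
        r = obs.surface_tension(traj, window=1.0)
        assert r.warnings

    def test_interfacial_uses_mean_fluctuating_length(self):
        # constant anisotropy 100 bar, <L_z> = 100 Å -> 50 mN/m
        p = np.diag([0.0, 0.0, 100.0])
        traj = Trajectory(sampling_interval=10.0)
        rng = np.random.default_rng(2)
        lz_values = 100.0 + rng.normal(scale=3.0, size=12)
        lz_values -= lz_values.mean() - 100.0  # exact mean 100
        for k, lz in enumerate(lz_values):
            f = Frame(rng.random((8, 3)) * [40, 40, 40], np.zeros((8, 3)),
                      np.array([40.0, 40.0, lz]), 10.0 * (k + 1), ["A"] * 8)
            traj.append(f, 0, 0, 0, p, np.zeros(2))
        r = obs.interfacial_tension(traj, window=1.0)
        assert r.value == pytest.approx(50.0, rel=1e-9)

    def test_frame_duplication_keeps_value_shrinks_error(self):
        rng = np.random.default_rng(4)
        ps = np.array([np.diag(rng.normal(100, 15, 3)) for _ in range(10)])
        t1 = synthetic_traj(10, [40, 40, 100], ptens=ps)
        t2 = synthetic_traj(20, [40, 40, 100], ptens=np.repeat(ps, 2, axis=0))
        a = obs.interfacial_tension(t1, window=1.0)
        b = obs.interfacial_tension(t2, window=1.0)
        assert b.value == pytest.approx(a.value, rel=1e-9)
        assert b.uncertainty <= a.uncertainty + 1e-12


class TestOsmoticPressure:
    def test_zero_without_crossings(self):
        traj = synthetic_traj(10, [100, 50, 50], wall=np.zeros((10, 2)))
        r = obs.osmotic_pressure(traj, window=1.0)
        assert r.value == 0.0

    def test_hand_conversion_to_bar(self):
        # 20 kcal/mol/Å on 50×50 Å² -> ≈ 555.8 bar
        wall = np.full((10, 2), 20.0)
        traj = synthetic_traj(10, [100, 50, 50], wall=wall)
        r = obs.osmotic_pressure(traj, window=1.0)
        assert r.value == pytest.approx(555.8, abs=0.1)

    def test_missing_wall_channels_raise(self):
        traj = synthetic_traj(10, [100, 50, 50], wall=np.zeros((10, 1)))
        with pytest.raises(ValueError, match="wall"):
            obs.osmotic_pressure(traj, n_walls=2, window=1.0)


class TestBilayerMetrics:
    def test_apl_direct_arithmetic(self):
        traj = synthetic_traj(5, [64.0, 64.0, 80.0])
        r = obs.area_per_lipid(traj, 128, window=1.0)
        assert r.value == pytest.approx(32.0, rel=1e-12)
        assert r.uncertainty == 0.0

    def test_apl_halves_when_nlpl_doubles(self):
        traj = synthetic_traj(5, [64.0, 64.0, 80.0])
        a = obs.area_per_lipid(traj, 64, window=1.0)
        b = obs.area_per_lipid(traj, 128, window=1.0)
        assert a.value == pytest.approx(2 * b.value)

    def test_apl_rejects_nonpositive_count(self):
        traj = synthetic_traj(5, [64.0, 64.0, 80.0])
        with pytest.raises(ValueError):
            obs.area_per_lipid(traj, 0)

    def _four_lipid_traj(self):
        # heads at z = 60 (upper) and z = 20 (lower), unequal masses
        pos = np.array([[10.0, 10, 60], [30.0, 30, 60],
                        [10.0, 30, 20], [30.0, 10, 20],
                        [20.0, 20, 40]])  # a tail bead, not selected
        return synthetic_traj(4, [40, 40, 80], positions=pos,
                              names=["H"] * 4 + ["T"])

    def test_headgroup_distance_hand_com(self):
        traj = self._four_lipid_traj()
        r = obs.headgroup_distance(traj, np.arange(4), window=1.0)
        assert r.value == pytest.approx(40.0, rel=1e-12)

    def test_headgroup_distance_weighted_com_matches_hand_value(self):
        traj = self._four_lipid_traj()
        masses = np.array([100.0, 50.0, 80.0, 40.0, 999.0])
        r = obs.headgroup_distance(traj, np.arange(4), masses=masses,
                                   window=1.0)
        assert r.value == pytest.approx(40.0, rel=1e-12)  # same z per leaflet

    def test_translation_invariance(self):
        traj = self._four_lipid_traj()
        shifted = synthetic_traj(
            4, [40, 40, 80],
            positions=traj.frames[0].positions + np.array([3.0, -2.0, 7.5]),
            names=["H"] * 4 + ["T"])
        a = obs.headgroup_distance(traj, np.arange(4), window=1.0)
        b = obs.headgroup_distance(shifted, np.arange(4), window=1.0)
        assert a.value == pytest.approx(b.value, rel=1e-12)

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError, match="empty"):
            obs.headgroup_distance(self._four_lipid_traj(), np.array([]))


def bond_traj(directions, box=200.0):
    """One frame; each chain is a single bond with the given direction."""
    d = np.asarray(directions, dtype=float)
    n = len(d)
    base = np.column_stack([np.linspace(10, box - 10, n),
                            np.full(n, box / 2), np.full(n, box / 2)])
    pos = np.empty((2 * n, 3))
    pos[0::2] = base
    pos[1::2] = base + d
    chains = np.array([[[2 * i, 2 * i + 1]] for i in range(n)])
    traj = synthetic_traj(1, [box] * 3, positions=pos,
                          names=["A"] * (2 * n))
    return traj, chains


class TestOrderParameters:
    def test_parallel_bonds_give_one(self):
        traj, chains = bond_traj([[0, 0, 2.0]] * 10)
        s = obs.order_parameters(traj, chains, window=1.0)
        assert s[0].value == pytest.approx(1.0, rel=1e-12)

    def test_perpendicular_bonds_give_minus_half(self):
        traj, chains = bond_traj([[2.0, 0, 0]] * 5 + [[0, 2.0, 0]] * 5)
        s = obs.order_parameters(traj, chains, window=1.0)
        assert s[0].value == pytest.approx(-0.5, rel=1e-12)

    def test_isotropic_bonds_average_to_zero(self):
        # Monte-Carlo oracle: <cos²θ> = 1/3 on the sphere
        rng = np.random.default_rng(8)
        v = rng.normal(size=(100_000, 3))
        v = 2.0 * v / np.linalg.norm(v, axis=1)[:, None]
        traj, chains = bond_traj(v, box=1e6)
        s = obs.order_parameters(traj, chains, window=1.0)
        assert abs(s[0].value) < 0.01

    def test_zero_length_bond_excluded_with_warning(self):
        traj, chains = bond_traj([[0, 0, 2.0], [0, 0, 0.0]])
        s = obs.order_parameters(traj, chains, window=1.0)
        assert s[0].warnings
        assert s[0].value == pytest.approx(1.0)


@given(st.lists(st.tuples(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)),
                min_size=4, max_size=40))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_order_parameter_bounded_for_arbitrary_bonds(vecs):
    """S ∈ [-0.5, 1] for any set of nonzero bond vectors."""
    d = np.asarray(vecs)
    d = d[np.linalg.norm(d, axis=1) > 1e-3]
    if len(d) == 0:
        return
    traj, chains = bond_traj(d * 3.0, box=1e5)
    s = obs.order_parameters(traj, chains, window=1.0)
    assert -0.5 - 1e-9 <= s[0].value <= 1.0 + 1e-9


class TestDensityProfile:
    def test_uniform_gas_profile_flat_within_poisson(self):
        rng = np.random.default_rng(9)
        box = np.array([30.0, 30.0, 60.0])
        traj = Trajectory(sampling_interval=1.0)
        n = 3000
        for k in range(5):
            f = Frame(rng.random((n, 3)) * box, np.zeros((n, 3)), box,
                      k + 1.0, ["A"] * n)
            traj.append(f, 0, 0, 0, np.zeros((3, 3)), np.zeros(2))
        centers, rho = obs.density_profile(traj, "z", np.arange(n), 5.0,
                                           window=1.0)
        mean = n / box.prod()
        per_bin = n * 5 * 5.0 * 30 * 30 / box.prod()
        assert np.all(np.abs(rho - mean) < 5 * mean / np.sqrt(per_bin))

    def test_profile_integral_recovers_count(self):
        rng = np.random.default_rng(10)
        box = np.array([20.0, 20.0, 50.0])
        pos = rng.random((500, 3)) * box
        traj = synthetic_traj(3, box, positions=pos, names=["A"] * 500)
        sel = np.arange(120)
        centers, rho = obs.density_profile(traj, "z", sel, 2.0, window=1.0)
        bin_vol = (centers[1] - centers[0]) * 20.0 * 20.0
        assert np.sum(rho) * bin_vol == pytest.approx(120, rel=1e-9)

    def test_empty_selection_gives_zero_profile(self):
        traj = synthetic_traj(3, [20, 20, 50], n=50)
        _, rho = obs.density_profile(traj, "z", np.array([], dtype=int), 2.0,
                                     window=1.0)
        assert np.all(rho == 0.0)


class TestBlockError:
    def test_constant_series_has_zero_error(self):
        assert obs.block_error(np.full(100, 3.14)) == 0.0

    def test_iid_normal_matches_sampling_theory(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=100_000)
        # SE of 50 block means of 2000 points each: sigma/sqrt(N_total)
        est = obs.block_error(x, n_blocks=50)
        assert est == pytest.approx(1.0 / np.sqrt(100_000), rel=0.2)

    def test_permutation_within_blocks_leaves_error_unchanged(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=1000)
        e1 = obs.block_error(x, 5)
        y = x.copy()
        for b in range(5):
            seg = slice(200 * b, 200 * (b + 1))
            y[seg] = rng.permutation(y[seg])
        assert obs.block_error(y, 5) == pytest.approx(e1, rel=1e-12)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError, match="too short"):
            obs.block_error([1.0, 2.0], 5)


def test_bilayer_metrics_pipeline_on_simulated_toy_membrane():
    """Full chain: build toy bilayer -> short NVT -> APL, D_HH, order
    parameters via the bundle-derived selections."""
    from cgbrine import EnsembleSpec, Simulation
    from cgbrine import sysgen
    from cgbrine.forcefield import ElectrostaticsSpec
    from cgbrine.system import CompositionSpec

    bundle = sysgen.make_toy_bilayer(16, CompositionSpec(0.5, "bare"), seed=5)
    ff = sysgen.default_forcefield("bare", include_lipid=True,
                                   electrostatics=ElectrostaticsSpec(
                                       method="cutoff_shifted",
                                       real_space_cutoff=9.0))
    sim = Simulation(bundle.frame, ff, EnsembleSpec("NVT", temperature=298.0,
                                                    dt=5.0, seed=6),
                     topology=bundle.topology)
    sim.minimize(max_steps=30)
    sim.initialize_velocities()
    traj = sim.run(300, 20)
    masses = np.array([ff.mass(t) for t in bundle.frame.type_names])
    m = obs.bilayer_metrics(traj, 16, sysgen.head_indices(bundle),
                            sysgen.chain_definitions(bundle), masses=masses,
                            window=0.5)
    assert m.apl.value > 0
    assert 10.0 < m.d_hh.value < 60.0
    for pos, s in m.order.items():
        assert -0.5 <= s.value <= 1.0
    # a freshly built bilayer is strongly ordered along the normal
    assert m.order[0].value > 0.5
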