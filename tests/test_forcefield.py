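"""Unit tests for the interaction model: LJ forms, Coulomb term, bonded
terms, scaling, validation and serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgbrine import (AngleSpec, BeadType, BondSpec, BondedParams,
                     ElectrostaticsSpec, ForceFieldTable, PairPotential,
                     ScalingFactors, apply_scaling, bonded_energy_force,
                     coulomb_energy_force, pair_energy_force, validate_table)
from cgbrine.system import Topology


class TestLJForms:
    @pytest.mark.parametrize("form", ["lj9_6", "lj12_4"])
    @pytest.mark.parametrize("eps,sig", [(0.1, 3.0), (0.895, 4.371), (2.0, 6.0)])
    def test_zero_crossing_at_sigma(self, form, eps, sig):
        p = PairPotential("A", "B", eps, sig, form)
        u, _ = pair_energy_force(sig, p)
        assert u == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("form,rmin_factor", [
        ("lj9_6", (1.5) ** (1 / 3)), ("lj12_4", 3.0 ** 0.125)])
    @pytest.mark.parametrize("eps,sig", [(0.25, 3.5), (1.2, 5.0)])
    def test_well_depth_is_minus_epsilon_at_analytic_minimum(
            self, form, rmin_factor, eps, sig):
        p = PairPotential("A", "B", eps, sig, form)
        u, f = pair_energy_force(rmin_factor * sig, p)
        assert u == pytest.approx(-eps, rel=1e-12)
        assert f == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("form", ["lj9_6", "lj12_4"])
    def test_force_matches_finite_difference_on_grid(self, form):
        p = PairPotential("A", "B", 0.7, 4.2, form)
        r = np.linspace(0.8 * p.sigma, 3.0 * p.sigma, 50)
        h = 1e-6
        _, f = pair_energy_force(r, p)
        up, _ = pair_energy_force(r + h, p)
        um, _ = pair_energy_force(r - h, p)
        fd = -(up - um) / (2 * h)
        assert np.max(np.abs(f - fd) / np.maximum(np.abs(fd), 1e-10)) < 1e-6

    def test_zero_beyond_cutoff_and_domain_error_at_contact(self):
        p = PairPotential("A", "B", 0.5, 4.0)
        u, f = pair_energy_force(20.0, p, cutoff=15.0)
        assert u == 0.0 and f == 0.0
        with pytest.raises(ValueError, match="overlapping"):
            pair_energy_force(0.0, p)


class TestCoulomb:
    def test_neutral_bead_contributes_nothing(self):
        es = ElectrostaticsSpec()
        assert coulomb_energy_force(5.0, 0.0, 1.0, es) == (0.0, 0.0)

    def test_bare_screened_value_at_cutoff_distance(self):
        # C q_i q_j / (eps_r r) with C = 332.0637 kcal·Å/(mol e²)
        es = ElectrostaticsSpec(relative_permittivity=80.0)
        u, _ = coulomb_energy_force(15.0, +1.0, -1.0, es, term="bare")
        assert u == pytest.approx(-0.2767, abs=2e-4)

    def test_force_shifted_vanishes_at_cutoff(self):
        es = ElectrostaticsSpec(method="cutoff_shifted", real_space_cutoff=10.0)
        u, f = coulomb_energy_force(10.0, 1.0, 1.0, es)
        assert abs(u) < 1e-12 and abs(f) < 1e-12


class TestBonded:
    def _topology(self):
        return Topology(["CT"] * 3, np.array([[0, 1], [1, 2]]),
                        [("CT", "CT")] * 2, np.array([[0, 1, 2]]),
                        [("CT", "CT", "CT")])

    def _params(self, half=False):
        bp = BondedParams(half_factor=half)
        bp.add_bond(BondSpec("CT", "CT", 6.16, 3.65))
        bp.add_angle(AngleSpec("CT", "CT", "CT", 1.19, 160.0, corr_enabled=False))
        return bp

    def test_equilibrium_geometry_has_zero_energy_and_force(self):
        bp = self._params()
        th = math.radians(160.0)
        pos = np.array([[10.0, 10, 10], [13.65, 10, 10],
                        [13.65 - 3.65 * math.cos(th), 10 + 3.65 * math.sin(th), 10]])
        e, f = bonded_energy_force(pos, np.array([50.0] * 3), self._topology(), bp)
        assert e == pytest.approx(0.0, abs=1e-20)
        assert np.max(np.abs(f)) < 1e-9

    def test_forces_match_finite_difference(self):
        bp = self._params()
        rng = np.random.default_rng(3)
        pos = np.array([[10.0, 10, 10], [13.0, 11, 10.4], [15.5, 13.0, 11.2]])
        pos += rng.normal(scale=0.3, size=pos.shape)
        box = np.array([50.0] * 3)
        topo = self._topology()
        e, f = bonded_energy_force(pos, box, topo, bp)
        h = 1e-6
        for i in range(3):
            for a in range(3):
                pp = pos.copy(); pp[i, a] += h
                pm = pos.copy(); pm[i, a] -= h
                ep, _ = bonded_energy_force(pp, box, topo, bp)
                em, _ = bonded_energy_force(pm, box, topo, bp)
                assert f[i, a] == pytest.approx(-(ep - em) / (2 * h), rel=1e-6,
                                                abs=1e-8)

    def test_half_factor_convention_halves_energy(self):
        pos = np.array([[10.0, 10, 10], [14.0, 10, 10], [18.0, 10, 10.5]])
        box = np.array([50.0] * 3)
        topo = self._topology()
        e_full, _ = bonded_energy_force(pos, box, topo, self._params(False))
        e_half, _ = bonded_energy_force(pos, box, topo, self._params(True))
        assert e_half == pytest.approx(0.5 * e_full, rel=1e-12)

    def test_one_three_correction_is_repulsive_only(self):
        ff = ForceFieldTable()
        ff.add_bead(BeadType("CT", 42.0, 0.0, "alkane"))
        ff.add_pair(PairPotential("CT", "CT", 0.469, 4.506))
        bp = BondedParams()
        bp.add_bond(BondSpec("CT", "CT", 6.16, 3.65))
        bp.add_angle(AngleSpec("CT", "CT", "CT", 1.19, 160.0, corr_enabled=True))
        topo = self._topology()
        box = np.array([50.0] * 3)
        # collapsed angle: 1-3 distance well below the LJ minimum
        pos_folded = np.array([[10.0, 10, 10], [13.0, 10, 10], [10.5, 11.0, 10]])
        e_corr, _ = bonded_energy_force(pos_folded, box, topo, bp, ff.get_pair)
        bp2 = self._params(False)
        e_plain, _ = bonded_energy_force(pos_folded, box, topo, bp2)
        assert e_corr > e_plain  # the correction penalizes the collapse
        # open geometry: correction inactive
        pos_open = np.array([[10.0, 10, 10], [13.65, 10, 10], [17.2, 11.0, 10]])
        e1, _ = bonded_energy_force(pos_open, box, topo, bp, ff.get_pair)
        bp_nocorr = BondedParams()
        bp_nocorr.add_bond(BondSpec("CT", "CT", 6.16, 3.65))
        bp_nocorr.add_angle(AngleSpec("CT", "CT", "CT", 1.19, 160.0,
                                      corr_enabled=False))
        e2, _ = bonded_energy_force(pos_open, box, topo, bp_nocorr, ff.get_pair)
        assert e1 == pytest.approx(e2, rel=1e-12)


class TestScaling:
    def _table(self):
        ff = ForceFieldTable()
        ff.add_bead(BeadType("SOD", 23.0, 1.0, "cation"))
        ff.add_bead(BeadType("CT", 42.0, 0.0, "alkane"))
        ff.add_pair(PairPotential("SOD", "SOD", 0.35, 2.6))
        ff.add_pair(PairPotential("CT", "CT", 0.469, 4.5))
        ff.add_pair(PairPotential("SOD", "CT", 0.4, 3.5))
        return ff

    def test_identity_scaling_returns_equal_table(self):
        ff = self._table()
        s = ScalingFactors(1.0, 1.0, (("@cation", "@alkane"),))
        assert apply_scaling(ff, s) == ff

    def test_scaling_is_local_to_selected_pairs(self):
        ff = self._table()
        s = ScalingFactors(2.0, 1.0, (("@cation", "@alkane"),))
        out = apply_scaling(ff, s)
        assert out.pair("SOD", "CT").epsilon == pytest.approx(0.8)
        assert out.pair("SOD", "CT").sigma == pytest.approx(3.5)
        assert out.pair("SOD", "SOD") == ff.pair("SOD", "SOD")
        assert out.pair("CT", "CT") == ff.pair("CT", "CT")

    def test_inverse_composition_recovers_original(self):
        ff = self._table()
        s = ScalingFactors(1.7, 1.3, (("@cation", "@alkane"),))
        inv = ScalingFactors(1 / 1.7, 1 / 1.3, (("@cation", "@alkane"),))
        back = apply_scaling(apply_scaling(ff, s), inv)
        p, q = back.pair("SOD", "CT"), ff.pair("SOD", "CT")
        assert p.epsilon == pytest.approx(q.epsilon, rel=1e-14)
        assert p.sigma == pytest.approx(q.sigma, rel=1e-14)

    def test_empty_selector_match_raises(self):
        with pytest.raises(ValueError, match="matched no pairs"):
            apply_scaling(self._table(),
                          ScalingFactors(2.0, 1.0, (("@water", "@anion"),)))


class TestTableValidation:
    def test_complete_table_gives_empty_report(self, ionic_ff):
        assert validate_table(ionic_ff, ["P", "M", "P"]).ok

    def test_missing_cross_pair_reported_once(self, ionic_ff):
        del ionic_ff.pairs[("M", "P")]
        rep = validate_table(ionic_ff, ["P", "M"])
        assert [f.kind for f in rep.findings] == ["missing_pair"]
        assert "M-P" in rep.findings[0].detail

    def test_injected_invalid_epsilon_reported(self, ionic_ff):
        bad = ionic_ff.pairs[("P", "P")]
        object.__setattr__(bad, "epsilon", -1.0)  # bypass constructor checks
        rep = validate_table(ionic_ff, ["P"])
        assert any(f.kind == "invalid_parameter" for f in rep.findings)

    def test_pair_lookup_is_symmetric(self, ionic_ff):
        assert ionic_ff.pair("P", "M") is ionic_ff.pair("M", "P")

    def test_lorentz_berthelot_fallback_warns(self, ionic_ff):
        del ionic_ff.pairs[("M", "P")]
        ionic_ff.allow_lorentz_berthelot = True
        with pytest.warns(UserWarning, match="Lorentz"):
            p = ionic_ff.pair("P", "M")
        assert p.sigma == pytest.approx(3.5)


class TestSerialization:
    def test_round_trip_reproduces_every_field_exactly(self):
        ff = ForceFieldTable(electrostatics=ElectrostaticsSpec(
            77.3, "cutoff_shifted", 11.25))
        ff.add_bead(BeadType("W", 54.04584, 0.0, "water", 3))
        ff.add_bead(BeadType("SOD", 22.9898, 1.0, "cation", 0))
        ff.add_pair(PairPotential("W", "W", 0.895, 4.371, "lj12_4"))
        ff.add_pair(PairPotential("W", "SOD", 0.8123456789012345, 4.0, "lj12_4"))
        ff.add_pair(PairPotential("SOD", "SOD", 0.35, 2.6))
        ff.bonded.add_bond(BondSpec("W", "W", 6.16, 3.65))
        ff.bonded.add_angle(AngleSpec("W", "W", "W", 1.19, 173.0, False))
        ff.bonded.half_factor = True
        back = ForceFieldTable.from_text(ff.to_text())
        assert back == ff
        assert back.to_text() == ff.to_text()

    def test_replace_pair_touches_only_target(self, ionic_ff):
        out = ionic_ff.replace_pair("P", "M", epsilon=0.99)
        assert out.pair("P", "M").epsilon == 0.99
        assert out.pair("P", "M").sigma == ionic_ff.pair("P", "M").sigma
        assert out.pair("P", "P") == ionic_ff.pair("P", "P")
        assert ionic_ff.pair("P", "M").epsilon == 0.35  # original untouched


@given(eps=st.floats(0.01, 5.0), sig=st.floats(1.0, 8.0),
       x=st.floats(0.7, 4.0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_lj_forms_bounded_below_by_minus_epsilon(eps, sig, x):
    """Neither LJ variant ever drops below its well depth -eps."""
    for form in ("lj9_6", "lj12_4"):
        u, _ = pair_energy_force(x * sig, PairPotential("A", "B", eps, sig, form))
        assert u >= -eps * (1 + 1e-9)
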