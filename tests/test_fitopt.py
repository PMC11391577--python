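"""Optimizer logic: BO on analytic objectives, objective semantics,
condition-2 locality, deviation reports."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cgbrine import fitopt, sysgen
from cgbrine.forcefield import ElectrostaticsSpec
from cgbrine.fitopt import (FitConfig, FreeParameter,
                            ParamSpace, QuadraticSurrogate,
                            TargetUnreachableError, bayesian_optimize,
                            condition2_tune, deviation_report)

warnings.filterwarnings("ignore", category=UserWarning)


def _space2d(lo=(0.0, 3.0), hi=(1.0, 6.0)):
    return ParamSpace([FreeParameter(("W", "SOD"), "epsilon", lo[0], hi[0]),
                       FreeParameter(("W", "SOD"), "sigma", lo[1], hi[1])])


class TestBayesianOptimize:
    def test_quadratic_minimum_found_within_tolerance(self):
        obj = QuadraticSurrogate(np.array([0.5, 4.0]))
        res = bayesian_optimize(obj, _space2d(),
                                FitConfig(n_initial=10, n_iterations=30, seed=0))
        assert np.hypot(*(res.best_x - [0.5, 4.0])) < 0.05
        assert len(res.trace_y) == 40

    def test_best_so_far_trace_monotone_nonincreasing(self):
        obj = QuadraticSurrogate(np.array([0.3, 5.0]))
        res = bayesian_optimize(obj, _space2d(),
                                FitConfig(n_initial=5, n_iterations=15, seed=1))
        assert np.all(np.diff(res.best_so_far) <= 0)
        assert res.best_objective == res.trace_y.min()

    def test_same_seed_reproduces_trace(self):
        obj = QuadraticSurrogate(np.array([0.7, 3.5]))
        cfg = FitConfig(n_initial=6, n_iterations=8, seed=3)
        a = bayesian_optimize(obj, _space2d(), cfg)
        b = bayesian_optimize(obj, _space2d(), cfg)
        assert np.array_equal(a.trace_x, b.trace_x)
        assert np.array_equal(a.trace_y, b.trace_y)

    def test_lcb_acquisition_also_converges(self):
        obj = QuadraticSurrogate(np.array([0.5, 4.0]))
        res = bayesian_optimize(
            obj, _space2d(), FitConfig(n_initial=10, n_iterations=30, seed=2,
                                       acquisition="lower_confidence_bound"))
        assert np.hypot(*(res.best_x - [0.5, 4.0])) < 0.15

    def test_all_penalty_evaluations_raise_with_trace(self):
        res = None
        with pytest.raises(fitopt.AllEvaluationsFailedError) as exc:
            bayesian_optimize(lambda x: fitopt.PENALTY, _space2d(),
                              FitConfig(n_initial=4, n_iterations=2, seed=0))
        assert len(exc.value.trace_y) >= 4


class TestCondition1Objective:
    @pytest.fixture(scope="class")
    def setup(self):
        es = ElectrostaticsSpec(method="cutoff_shifted", real_space_cutoff=9.0)
        ff = sysgen.default_forcefield("solvated", electrostatics=es)
        conc = np.array([1.0])
        kw = dict(ff=ff, seed=0, total_beads=120, n_steps=150, sample_every=5)
        tgt_d = sysgen.simulate_ground_truth_targets("density", conc, **kw)
        tgt_g = sysgen.simulate_ground_truth_targets("surface_tension", conc, **kw)
        budget = fitopt.SimBudget(total_beads=120, n_steps=150, sample_every=5)
        return ff, [tgt_d, tgt_g], budget

    def test_self_consistency_gives_zero(self, setup):
        ff, targets, budget = setup
        assert fitopt.condition1_objective(ff, targets, budget, seed=0) == 0.0

    def test_zero_density_weight_ignores_density_deviation(self, setup):
        ff, targets, budget = setup
        # shift the density targets only; with w_density = 0 the objective
        # must not change
        t_d, t_g = targets
        t_d_shifted = sysgen.TargetCurve(t_d.property, t_d.molarities,
                                         t_d.values + 100.0, t_d.uncertainties,
                                         t_d.units, t_d.provenance)
        a = fitopt.condition1_objective(ff, [t_d, t_g], budget,
                                        w_density=0.0, seed=0)
        b = fitopt.condition1_objective(ff, [t_d_shifted, t_g], budget,
                                        w_density=0.0, seed=0)
        assert a == b == 0.0

    def test_analytic_surrogate_equals_hand_weighted_sum(self):
        w = np.array([2.0, 0.5])
        obj = QuadraticSurrogate(np.array([1.0, 2.0]), weights=w)
        x = np.array([1.5, 1.0])
        assert obj(x) == pytest.approx(2.0 * 0.25 + 0.5 * 1.0)


class TestCondition2:
    def _ff(self, eps_sc=0.4):
        es = ElectrostaticsSpec(method="cutoff_shifted", real_space_cutoff=9.0)
        ff = sysgen.default_forcefield("bare", electrostatics=es)
        return ff.replace_pair("SOD", "CLA", epsilon=eps_sc)

    @staticmethod
    def analytic_pi(ff):
        # monotone decreasing surrogate response: stronger cross
        # attraction pairs up ions and lowers the osmotic pressure
        p = ff.pair("SOD", "CLA")
        return 300.0 * np.exp(-2.0 * p.epsilon) * (p.sigma / 3.1) ** 0.5

    def test_fixed_point_leaves_parameters_unchanged(self):
        ff = self._ff()
        pi0 = self.analytic_pi(ff)
        res = condition2_tune(ff, (5.0, pi0), pi_evaluator=self.analytic_pi)
        assert not res.changed
        assert res.table.pair("SOD", "CLA") == ff.pair("SOD", "CLA")

    def test_only_cross_pair_changes_field_by_field(self):
        ff = self._ff(0.4)
        target = self.analytic_pi(self._ff(0.9))
        res = condition2_tune(ff, (5.0, target), pi_evaluator=self.analytic_pi)
        assert res.changed
        for key, p in ff.pairs.items():
            if key == ("CLA", "SOD"):
                assert res.table.pairs[key] != p
            else:
                assert res.table.pairs[key] == p  # bitwise-equal dataclasses
        assert res.table.bead_types == ff.bead_types
        assert res.table.electrostatics == ff.electrostatics

    def test_achieves_target_within_tolerance(self):
        ff = self._ff(0.4)
        target = self.analytic_pi(self._ff(0.9))
        res = condition2_tune(ff, (5.0, target), tol=0.05,
                              pi_evaluator=self.analytic_pi)
        assert abs(res.pi_achieved - target) / target <= 0.05

    def test_unreachable_target_reports_closest(self):
        ff = self._ff(0.4)
        with pytest.raises(TargetUnreachableError) as exc:
            condition2_tune(ff, (5.0, 1e6), pi_evaluator=self.analytic_pi,
                            max_iter=15)
        assert np.isfinite(exc.value.closest_pi)
        assert len(exc.value.path) > 1

    def test_missing_cross_pair_rejected(self):
        ff = self._ff()
        del ff.pairs[("CLA", "SOD")]
        with pytest.raises(KeyError, match="SOD"):
            condition2_tune(ff, (5.0, 100.0), pi_evaluator=self.analytic_pi)


class TestDeviationReport:
    def _targets(self):
        return [sysgen.reference_targets("density",
                                         concentrations=np.array([1.0, 2.0]))]

    def test_exact_match_gives_zero_deviations(self):
        t = self._targets()
        rep = deviation_report({"density": t[0].values.copy()}, t)
        assert np.all(rep["rel_dev"] == 0.0)
        assert np.all(rep["max_rel_dev"] == 0.0)

    def test_single_point_off_by_ten_percent(self):
        t = self._targets()
        sim = t[0].values.copy()
        sim[1] *= 1.10
        rep = deviation_report({"density": sim}, t)
        assert rep["max_rel_dev"].iloc[0] == pytest.approx(0.10, rel=1e-9)
        assert rep["rel_dev"].iloc[0] == 0.0
        assert rep["rel_dev"].iloc[1] == pytest.approx(0.10, rel=1e-9)

    def test_report_is_deterministic(self):
        t = self._targets()
        sim = {"density": t[0].values * 1.02}
        a, b = deviation_report(sim, t), deviation_report(sim, t)
        pd.testing.assert_frame_equal(a, b)

    def test_final_model_rule_is_data(self):
        assert fitopt.FINAL_MODEL_RULE["solvated"]["stages"] == ("condition1",)
        assert "condition2" in fitopt.FINAL_MODEL_RULE["bare"]["stages"]


class TestParamSpace:
    def test_apply_sets_only_free_parameters(self):
        ff = sysgen.default_forcefield("bare")
        space = ParamSpace([FreeParameter(("W", "SOD"), "epsilon", 0.1, 2.0)])
        out = space.apply(ff, np.array([1.23]))
        assert out.pair("W", "SOD").epsilon == 1.23
        assert out.pair("W", "SOD").sigma == ff.pair("W", "SOD").sigma
        assert out.pair("W", "CLA") == ff.pair("W", "CLA")

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            FreeParameter(("W", "SOD"), "epsilon", 2.0, 1.0)
        with pytest.raises(ValueError):
            ParamSpace([])

    def test_unregistered_pair_rejected(self):
        ff = sysgen.default_forcefield("bare")
        space = ParamSpace([FreeParameter(("W", "XX"), "epsilon", 0.1, 1.0)])
        with pytest.raises(KeyError):
            space.validate_against(ff)


def test_evaluate_model_reports_zero_deviation_against_own_ground_truth():
    """evaluate_model run with the same table, seeds and budget that
    produced the targets yields an all-zero deviation surface."""
    es = ElectrostaticsSpec(method="cutoff_shifted", real_space_cutoff=9.0)
    ff = sysgen.default_forcefield("solvated", electrostatics=es)
    conc = np.array([1.0])
    tgt = sysgen.simulate_ground_truth_targets(
        "density", conc, ff=ff, seed=0, total_beads=120, n_steps=150,
        sample_every=5)
    rep = fitopt.evaluate_model(
        ff, [tgt], budget=fitopt.SimBudget(total_beads=120, n_steps=150,
                                           sample_every=5), seed=0)
    assert np.all(rep["rel_dev"] == 0.0)
    assert np.all(rep["max_rel_dev"] == 0.0)
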