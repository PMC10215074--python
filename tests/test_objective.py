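"""Surgical-target objectives, CMA-ES search, and clinical selection."""

import numpy as np
import pytest

from kneeplan import (ImplantPlacement, PlacementBounds, cma_minimize)
from kneeplan.forward_sim import SimulationTrace
from kneeplan.kinematics import Pose6
from kneeplan.knee_model import STRAIN_OBJECTIVE_NAMES
from kneeplan.objective import (CandidateRecord, ObjectiveSpec,
                                OptimizationResult, SurgicalTarget,
                                make_target, objective_value, optimize,
                                select_clinical, KINEMATIC_VARIABLES)

T_SAMPLES = 12
LIG7 = STRAIN_OBJECTIVE_NAMES


def synthetic_trace(kin_offset=0.0, strain_offset=0.0, strains=None,
                    converged=True, residual=0.1):
    """Hand-built trace on a small grid for exact objective arithmetic."""
    grid = np.linspace(60.0, 0.0, T_SAMPLES)
    poses = tuple(Pose6(fe=float(f)).with_free_coords(
        np.full(5, kin_offset)) for f in grid)
    if strains is None:
        strains = np.full((T_SAMPLES, 7), 0.02 + strain_offset)
    return SimulationTrace(
        flexion_deg=grid, poses=poses, strains=np.asarray(strains, float),
        ligament_names=LIG7,
        residuals=np.full(T_SAMPLES, residual),
        converged=np.full(T_SAMPLES, converged))


@pytest.fixture
def ref():
    return synthetic_trace()


class TestObjectiveValue:
    def test_matched_curves_give_zero(self, ref):
        spec = make_target(SurgicalTarget.ST1, None, ref)
        assert objective_value(synthetic_trace(), spec) == 0.0

    def test_unit_deviation_contributes_exactly_one(self, ref):
        # constant deviation 1.0 on every sample of one variable, w = 1:
        # (1/t) * t * 1^2 = 1 per deviating variable
        spec = ObjectiveSpec(("ap",), np.ones(1), ref)
        assert objective_value(synthetic_trace(kin_offset=1.0), spec) \
            == pytest.approx(1.0, abs=1e-15)

    def test_weight_scales_linearly(self, ref):
        spec1 = ObjectiveSpec(KINEMATIC_VARIABLES, np.ones(5), ref)
        spec2 = ObjectiveSpec(KINEMATIC_VARIABLES, 2 * np.ones(5), ref)
        tr = synthetic_trace(kin_offset=0.7)
        assert objective_value(tr, spec2) \
            == pytest.approx(2 * objective_value(tr, spec1), rel=1e-14)

    def test_residual_penalty_adds_exactly_1e3(self, ref):
        spec = make_target(SurgicalTarget.ST1, None, ref)
        clean = objective_value(synthetic_trace(kin_offset=0.5), spec)
        # any sample with residual above 5 N triggers the penalty once
        bad = synthetic_trace(kin_offset=0.5, residual=5.1)
        assert objective_value(bad, spec) == pytest.approx(clean + 1.0e3)
        unconv = synthetic_trace(kin_offset=0.5, converged=False)
        assert objective_value(unconv, spec) == pytest.approx(clean + 1.0e3)

    def test_peak_strain_penalty_adds_exactly_1e3(self, ref):
        spec = make_target(SurgicalTarget.ST4, None, ref)
        below = objective_value(synthetic_trace(strain_offset=-0.005), spec)
        assert below == pytest.approx(7 * 0.005 ** 2, rel=1e-12)  # no penalty
        above = synthetic_trace(strain_offset=0.001)   # exceeds the 0.02 peak
        assert objective_value(above, spec) \
            == pytest.approx(1.0e3 + 7 * 0.001 ** 2, rel=1e-9)

    def test_both_penalties_stack(self, ref):
        spec = make_target(SurgicalTarget.ST4, None, ref)
        tr = synthetic_trace(strain_offset=0.001, residual=6.0)
        bd = objective_value(tr, spec, return_breakdown=True)
        assert bd.residual_penalty and bd.peak_penalty
        assert bd.value == pytest.approx(bd.mismatch + 2.0e3)

    def test_grid_mismatch_rejected(self, ref):
        other = synthetic_trace()
        shifted = SimulationTrace(
            flexion_deg=other.flexion_deg + 0.5, poses=other.poses,
            strains=other.strains, ligament_names=other.ligament_names,
            residuals=other.residuals, converged=other.converged)
        spec = make_target(SurgicalTarget.ST1, None, ref)
        with pytest.raises(ValueError):
            objective_value(shifted, spec)


class TestMakeTarget:
    def test_st1_is_equal_weight_kinematics(self, ref):
        spec = make_target(SurgicalTarget.ST1, None, ref)
        assert spec.variables == KINEMATIC_VARIABLES
        np.testing.assert_array_equal(spec.weights, np.ones(5))

    def test_st2_is_equal_weight_strains(self, ref):
        spec = make_target(SurgicalTarget.ST2, None, ref)
        assert spec.variables == LIG7
        np.testing.assert_array_equal(spec.weights, np.ones(7))
        assert "ACL" not in spec.variables

    def test_st3_eightfold_collateral_weighting(self, ref):
        spec = make_target(SurgicalTarget.ST3, None, ref)
        w = dict(zip(spec.variables, spec.weights))
        assert [w[n] for n in ("sMCL", "dMCL", "LCL")] == [8.0] * 3
        assert sorted(spec.weights)[-3:] == [8.0] * 3
        assert sum(spec.weights) == 3 * 8 + 4

    def test_st4_thresholds_are_prediseased_peaks(self):
        rng = np.random.default_rng(0)
        strains = 0.03 * rng.standard_normal((T_SAMPLES, 7))
        ref = synthetic_trace(strains=strains)
        spec = make_target(SurgicalTarget.ST4, None, ref)
        for i, name in enumerate(LIG7):
            assert spec.peak_thresholds[name] == strains[:, i].max()

    def test_st5_blocks_contribute_equally_at_ma(self, ref):
        ma = synthetic_trace(kin_offset=1.3, strain_offset=0.012)
        spec = make_target(SurgicalTarget.ST5, ma, ref)
        bd = objective_value(ma, spec, return_breakdown=True)
        kin = bd.per_variable[:5].sum()
        strain = bd.per_variable[5:].sum()
        assert kin == pytest.approx(0.5, abs=1e-9)
        assert strain == pytest.approx(0.5, abs=1e-9)

    def test_st5_requires_ma_trace(self, ref):
        with pytest.raises(ValueError):
            make_target(SurgicalTarget.ST5, None, ref)


class TestCmaEs:
    def test_quadratic_recovered_to_1e3(self):
        x_opt = np.array([0.3, -0.5, 0.1, 0.6, -0.2, 0.0, 0.4, -0.7, 0.2])
        fun = lambda z: float(((z - x_opt) ** 2).sum())
        res = cma_minimize(fun, np.zeros(9), sigma0=0.25, popsize=16,
                           bounds=(-np.ones(9), np.ones(9)), seed=1,
                           max_evals=4000, ftarget=1e-10)
        np.testing.assert_allclose(res.xbest, x_opt, atol=1e-3)

    def test_reproducible_given_seed(self):
        fun = lambda z: float((z ** 2).sum())
        r1 = cma_minimize(fun, np.ones(4), 0.3, popsize=8, seed=5, max_evals=200)
        r2 = cma_minimize(fun, np.ones(4), 0.3, popsize=8, seed=5, max_evals=200)
        assert (r1.history_x == r2.history_x).all()
        assert r1.fbest == r2.fbest

    def test_all_candidates_recorded(self):
        fun = lambda z: float((z ** 2).sum())
        res = cma_minimize(fun, np.ones(3), 0.3, popsize=6, seed=0, max_evals=60)
        assert len(res.history_f) == res.n_evals
        assert res.fbest == res.history_f.min()


class TestOptimizeHarness:
    """optimize() on a cheap analytic stand-in simulator."""

    @staticmethod
    def quadratic_simulator(x_opt):
        def sim(x: ImplantPlacement):
            dev = float(np.linalg.norm((x.as_array() - x_opt) / 6.0))
            return synthetic_trace(kin_offset=dev)
        return sim

    def test_best_never_worse_than_ma(self, ref):
        spec = make_target(SurgicalTarget.ST1, None, ref)
        sim = self.quadratic_simulator(np.array([2., -1, 1, 0.5, -2, 1, 2, -1, 0]))
        res = optimize(spec, PlacementBounds(), sim, seed=0, max_evals=220)
        f_ma = objective_value(sim(ImplantPlacement()), spec)
        assert res.best.value <= f_ma
        assert any(c.x.is_zero() for c in res.candidates)   # MA was evaluated

    def test_solution_space_frame_columns(self, ref):
        spec = make_target(SurgicalTarget.ST1, None, ref)
        sim = self.quadratic_simulator(np.zeros(9))
        res = optimize(spec, PlacementBounds(), sim, seed=0, max_evals=50)
        df = res.solution_space_frame()
        assert df.shape[1] == 11    # 9 parameters + objective + feasibility
        assert df["objective"].min() == res.best.value


class TestSelectClinical:
    @staticmethod
    def result_from(values_and_x):
        bounds = PlacementBounds()
        records = [CandidateRecord(x=ImplantPlacement.from_array(x), value=v,
                                   residual_penalty=False, peak_penalty=False)
                   for v, x in values_and_x]
        best = min(records, key=lambda r: r.value)
        return OptimizationResult(candidates=records, best=best, bounds=bounds,
                                  seed=0, n_generations=1, stop_reason="test")

    def test_tol_zero_returns_best(self):
        res = self.result_from([(1.0, np.ones(9)), (0.5, 2 * np.ones(9) / 2),
                                (2.0, np.zeros(9))])
        sel = select_clinical(res, tol_rel=0.0)
        assert sel.as_array() == pytest.approx(res.best.x.as_array())

    def test_ma_preferred_among_near_optima(self):
        res = self.result_from([(1.0, np.ones(9)), (1.01, np.zeros(9))])
        sel = select_clinical(res, tol_rel=0.05)
        assert sel.is_zero()

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(9)
        cands = [(float(rng.uniform(1, 2)), rng.uniform(-6, 6, 9) * [1, 1, 1, .5, 1, 1, 1, 1, 1])
                 for _ in range(200)]
        res = self.result_from(cands)
        tol = 0.25
        sel = select_clinical(res, tol_rel=tol)
        # exhaustive oracle over the stored candidate set
        hw = res.bounds.half_width
        cutoff = (1 + tol) * res.best.value
        qualifying = [c for c in res.candidates if c.value <= cutoff]
        oracle = min(qualifying,
                     key=lambda c: float(np.linalg.norm(c.x.as_array() / hw)))
        assert sel.as_array() == pytest.approx(oracle.x.as_array())
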