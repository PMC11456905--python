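import dataclasses

import numpy as np
import pytest

import liverspare as ls

from conftest import small_run_config


def _toy_geometry(n=20, spacing=2.5, n_beams=3, ptv_halfwidth=1):
    """Water box with a central PTV, a lateral FLV slab and an OAR block."""
    red = ls.VoxelImage(np.ones((n, n, 8)), (spacing, spacing, 5.0))
    c = n // 2
    masks = {}
    ptv = np.zeros(red.shape, bool)
    ptv[c - ptv_halfwidth : c + ptv_halfwidth, c - ptv_halfwidth : c + ptv_halfwidth, 3:5] = True
    masks["ptv"] = ptv
    flv = np.zeros(red.shape, bool)
    flv[2 : c - 3, :, 2:6] = True
    masks["flv"] = flv
    liver = flv.copy()
    liver[2 : c + 2, :, 2:6] = True
    masks["liver_minus_gtv"] = liver & ~ptv
    oar = np.zeros(red.shape, bool)
    oar[n - 4 : n - 2, c - 2 : c + 2, 3:5] = True
    masks["oar"] = oar
    iso = tuple(
        (idx.mean() + 0.5) * s for idx, s in zip(np.nonzero(ptv), red.spacing)
    )
    geom = ls.BeamGeometry(ls.beam_angles(n_beams, 168, 24), iso, beamlet_size_mm=5.0)
    D = ls.build_dose_influence(
        geom, red, ls.KernelParams(), ls.VoxelImage(ptv, red.spacing), margin_mm=5.0
    )
    return D, masks


class TestParallelDamage:
    def test_logistic_midpoint_at_reference_dose(self):
        assert ls.parallel_damage(np.full(50, 15.0), 15.0, 3.0) == pytest.approx(0.5)

    def test_zero_dose_zero_damage(self):
        assert ls.parallel_damage(np.zeros(10), 15.0, 3.0) == 0.0

    def test_half_at_reference_half_at_zero(self):
        d = np.concatenate([np.full(5, 15.0), np.zeros(5)])
        assert ls.parallel_damage(d, 15.0, 3.0) == pytest.approx(0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ls.parallel_damage(np.array([]), 15.0, 3.0)

    def test_monotone_in_dose(self, rng):
        d = rng.uniform(0, 40, 200)
        bumped = d + rng.uniform(0, 5, 200)
        assert ls.parallel_damage(bumped, 15.0, 3.0) >= ls.parallel_damage(d, 15.0, 3.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ls.parallel_damage(np.ones(3), 0.0, 3.0)
        with pytest.raises(ValueError):
            ls.ParallelObjective(d_ref_gy=15.0, k_power=-1.0)


class TestOptimizePlan:
    def test_single_voxel_ptv_reaches_prescription(self):
        # with only the PTV term the quadratic optimum is dose == Rx
        red = ls.VoxelImage(np.ones((16, 16, 6)), (3.0, 3.0, 5.0))
        ptv = np.zeros(red.shape, bool)
        ptv[8, 8, 3] = True
        iso = (25.5, 25.5, 17.5)
        geom = ls.BeamGeometry([0.0], iso, beamlet_size_mm=5.0)
        D = ls.build_dose_influence(geom, red, ls.KernelParams(), ls.VoxelImage(ptv, red.spacing))
        obj = ls.PlanObjectives(ptv_prescription_gy=50.0, liver_mean_weight=0.0)
        plan = ls.optimize_plan(D, {"ptv": ptv}, obj, max_iter=200)
        assert plan.dose.data[8, 8, 3] == pytest.approx(50.0, rel=0.005)

    def test_objective_trace_non_increasing(self):
        D, masks = _toy_geometry()
        obj = ls.PlanObjectives(ptv_prescription_gy=40.0)
        plan = ls.optimize_plan(D, masks, obj, max_iter=60)
        tr = plan.objective_trace
        assert all(b <= a for a, b in zip(tr, tr[1:]))

    def test_fluence_stays_non_negative(self):
        D, masks = _toy_geometry()
        obj = ls.PlanObjectives(ptv_prescription_gy=40.0)
        plan = ls.optimize_plan(D, masks, obj, max_iter=60)
        assert (plan.fluence >= 0).all()

    def test_zero_weight_sparing_identical_to_standard(self):
        D, masks = _toy_geometry()
        obj_std = ls.PlanObjectives(ptv_prescription_gy=40.0, flv_parallel=None)
        obj_zero = ls.PlanObjectives(
            ptv_prescription_gy=40.0, flv_parallel=ls.ParallelObjective(weight=0.0)
        )
        a = ls.optimize_plan(D, masks, obj_std, max_iter=50)
        b = ls.optimize_plan(D, masks, obj_zero, max_iter=50)
        assert np.array_equal(a.fluence, b.fluence)
        assert np.array_equal(a.dose.data, b.dose.data)

    def test_deterministic_for_fixed_inputs(self):
        D, masks = _toy_geometry()
        obj = ls.PlanObjectives(ptv_prescription_gy=40.0)
        a = ls.optimize_plan(D, masks, obj, max_iter=40)
        b = ls.optimize_plan(D, masks, obj, max_iter=40)
        assert np.array_equal(a.fluence, b.fluence)

    def test_sparing_reduces_flv_mean_dose(self):
        D, masks = _toy_geometry()
        obj = ls.PlanObjectives(ptv_prescription_gy=40.0)
        std = ls.optimize_plan(D, masks, obj, max_iter=80)
        spare = ls.auto_sparing_weight(
            D, masks, dataclasses.replace(obj, flv_parallel=ls.ParallelObjective()),
            d95_floor_gy=0.95 * 40.0, standard_plan=std, max_iter=80,
        )
        assert spare.meta["sparing_applied"]
        assert ls.mean_dose(spare.dose, masks["flv"]) < ls.mean_dose(std.dose, masks["flv"])
        assert spare.constraint_report["ptv_d95_gy"] >= 0.95 * 40.0


class TestAutoSparingWeight:
    def test_zero_floor_returns_top_of_ladder(self):
        D, masks = _toy_geometry()
        obj = ls.PlanObjectives(
            ptv_prescription_gy=40.0, flv_parallel=ls.ParallelObjective(weight=1.0)
        )
        plan = ls.auto_sparing_weight(
            D, masks, obj, d95_floor_gy=0.0, start_weight=10.0, max_steps=4, max_iter=30
        )
        assert plan.meta["sparing_weight"] == 10.0 * 2**3
        assert len(plan.meta["ladder"]) == 4

    def test_empty_flv_returns_standard_flagged(self):
        D, masks = _toy_geometry()
        masks = dict(masks, flv=np.zeros_like(masks["flv"]))
        obj = ls.PlanObjectives(
            ptv_prescription_gy=40.0, flv_parallel=ls.ParallelObjective(weight=1.0)
        )
        plan = ls.auto_sparing_weight(D, masks, obj, d95_floor_gy=38.0, max_iter=30)
        assert plan.meta["sparing_applied"] is False

    def test_unreachable_floor_returns_standard_flagged(self):
        D, masks = _toy_geometry()
        obj = ls.PlanObjectives(
            ptv_prescription_gy=40.0, flv_parallel=ls.ParallelObjective(weight=1.0)
        )
        plan = ls.auto_sparing_weight(
            D, masks, obj, d95_floor_gy=1e6, start_weight=10.0, max_iter=30
        )
        assert plan.meta["sparing_applied"] is False


class TestSelectPrescription:
    def test_single_tier_returned_regardless(self):
        D, masks = _toy_geometry()
        tiers = ls.PrescriptionTiers([{"rx_gy": 45.0, "lmd_limit_gy": 0.001}])
        rx, plan = ls.select_prescription(
            D, masks, tiers, ls.PlanObjectives(), max_iter=30
        )
        assert rx == 45.0

    def test_tight_top_tier_limit_falls_through_to_lower_tier(self):
        D, masks = _toy_geometry()
        tiers = ls.PrescriptionTiers(
            [{"rx_gy": 50.0, "lmd_limit_gy": 1e-6}, {"rx_gy": 40.0, "lmd_limit_gy": 1e6}]
        )
        rx, plan = ls.select_prescription(
            D, masks, tiers, ls.PlanObjectives(), max_iter=30
        )
        assert rx == 40.0

    def test_generous_limits_select_top_tier(self):
        D, masks = _toy_geometry()
        tiers = ls.PrescriptionTiers(
            [{"rx_gy": 50.0, "lmd_limit_gy": 1e6}, {"rx_gy": 40.0, "lmd_limit_gy": 1e6}]
        )
        rx, _ = ls.select_prescription(D, masks, tiers, ls.PlanObjectives(), max_iter=30)
        assert rx == 50.0

    def test_tier_ordering_validated(self):
        with pytest.raises(ValueError):
            ls.PrescriptionTiers([{"rx_gy": 40.0, "lmd_limit_gy": 1}, {"rx_gy": 50.0, "lmd_limit_gy": 1}])


class TestRescaleToD95:
    def _plan(self):
        D, masks = _toy_geometry()
        obj = ls.PlanObjectives(ptv_prescription_gy=40.0)
        return ls.optimize_plan(D, masks, obj, max_iter=50), masks

    def test_identity_rescale(self):
        plan, masks = self._plan()
        d95 = ls.dose_at_volume_percent(plan.dose, masks["ptv"], 95)
        out = ls.rescale_to_d95(plan, masks["ptv"], d95)
        assert np.allclose(out.dose.data, plan.dose.data)

    def test_target_hit_exactly(self):
        plan, masks = self._plan()
        out = ls.rescale_to_d95(plan, masks["ptv"], 42.0)
        assert ls.dose_at_volume_percent(out.dose, masks["ptv"], 95) == pytest.approx(
            42.0, rel=1e-6
        )

    def test_doubling_target_doubles_all_d_metrics(self):
        plan, masks = self._plan()
        d95 = ls.dose_at_volume_percent(plan.dose, masks["ptv"], 95)
        out = ls.rescale_to_d95(plan, masks["ptv"], 2 * d95)
        for p in (50, 95, 99):
            assert ls.dose_at_volume_percent(out.dose, masks["ptv"], p) == pytest.approx(
                2 * ls.dose_at_volume_percent(plan.dose, masks["ptv"], p), rel=1e-12
            )

    def test_zero_d95_rejected(self):
        plan, masks = self._plan()
        zero = dataclasses.replace(plan, dose=plan.dose.copy(data=np.zeros(plan.dose.shape)))
        with pytest.raises(ValueError):
            ls.rescale_to_d95(zero, masks["ptv"], 40.0)
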