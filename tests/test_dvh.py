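"""DVH curves, point-dose metrics, scorecard and report rendering."""

import json

import numpy as np
import pytest

import redose as rd
from redose.dvh import (
    evaluate_metric,
    metric_d_cc,
    metric_d_pct,
    metric_v_gy,
    render_report,
)
from redose.errors import ParameterError


def grid_with(geom, values):
    return rd.DoseGrid(geom, values, rd.DoseKind.EQD2)


def full_mask(geom, name="s"):
    return rd.StructureMask(name, geom, np.ones(geom.shape, bool))


class TestDvhCurve:
    def test_uniform_dose_is_step_function(self, small_geom):
        dose = grid_with(small_geom, np.full(small_geom.shape, 50.0))
        curve = rd.compute_dvh(dose, full_mask(small_geom), bin_width=1.0)
        assert curve.volume_at_dose(0.0) == 100.0
        assert curve.volume_at_dose(50.0) == 100.0
        assert curve.volume_at_dose(50.5) == 0.0

    def test_two_level_dose_fifty_percent_between(self, small_geom):
        vals = np.full(small_geom.shape, 20.0)
        vals[:5] = 60.0  # exactly half the voxels
        curve = rd.compute_dvh(grid_with(small_geom, vals), full_mask(small_geom), 1.0)
        for d in (21.0, 40.0, 60.0):
            assert curve.volume_at_dose(d) == pytest.approx(50.0)

    def test_curve_non_increasing_and_order_invariant(self, small_geom, rng):
        vals = rng.uniform(0, 70, small_geom.shape)
        curve = rd.compute_dvh(grid_with(small_geom, vals), full_mask(small_geom), 0.5)
        assert np.all(np.diff(curve.cumulative_volume_pct) <= 1e-12)
        shuffled = vals.reshape(-1).copy()
        rng.shuffle(shuffled)
        curve2 = rd.compute_dvh(grid_with(small_geom, shuffled.reshape(vals.shape)),
                                full_mask(small_geom), 0.5)
        np.testing.assert_allclose(curve.cumulative_volume_pct,
                                   curve2.cumulative_volume_pct)

    def test_dvh_metrics_consistent_with_direct(self, small_geom, rng):
        vals = rng.uniform(0, 70, small_geom.shape)
        dose = grid_with(small_geom, vals)
        mask = full_mask(small_geom)
        bw = 0.1
        curve = rd.compute_dvh(dose, mask, bw)
        dmax_dvh = curve.dose_bins[np.nonzero(curve.cumulative_volume_pct)[0][-1]]
        assert abs(dmax_dvh - vals.max()) <= bw
        # Dmean from the differential histogram matches the direct mean
        diff = -np.diff(curve.cumulative_volume_pct) / 100.0
        mids = curve.dose_bins[:-1] + bw / 2
        assert abs((diff * mids).sum() - vals.mean()) <= bw

    def test_empty_mask_rejected_by_name(self, small_geom):
        dose = grid_with(small_geom, np.zeros(small_geom.shape))
        empty = rd.StructureMask("cord", small_geom, np.zeros(small_geom.shape, bool))
        with pytest.raises(ParameterError, match="cord"):
            rd.compute_dvh(dose, empty, 0.1)


class TestDccMetric:
    def test_uniform_dose(self, small_geom):
        dose = grid_with(small_geom, np.full(small_geom.shape, 42.0))
        assert metric_d_cc(dose, full_mask(small_geom), 0.01) == 42.0

    def test_single_hot_voxel_below_hot_volume(self):
        # 1 mm voxels: one voxel (0.001 cc) at 70, the rest 30; D0.01cc = 30
        geom = rd.GridGeometry((0, 0, 0), (1, 1, 1), (10, 10, 10))
        vals = np.full(geom.shape, 30.0)
        vals[0, 0, 0] = 70.0
        assert metric_d_cc(grid_with(geom, vals), full_mask(geom), 0.01) == 30.0

    def test_ten_hot_voxels_reach_hot_volume(self):
        geom = rd.GridGeometry((0, 0, 0), (1, 1, 1), (10, 10, 10))
        vals = np.full(geom.shape, 30.0)
        vals.reshape(-1)[:10] = 70.0
        assert metric_d_cc(grid_with(geom, vals), full_mask(geom), 0.01) == 70.0

    def test_structure_smaller_than_volume_warns(self, small_geom):
        m = np.zeros(small_geom.shape, bool)
        m[0, 0, 0] = True  # 0.001 cc structure
        vals = np.full(small_geom.shape, 12.0)
        with pytest.warns(UserWarning, match="cc"):
            v = metric_d_cc(grid_with(small_geom, vals),
                            rd.StructureMask("tiny", small_geom, m), 0.01)
        assert v == 12.0

    def test_agrees_with_brute_force_oracle(self, rng):
        geom = rd.GridGeometry((0, 0, 0), (1.7, 2.1, 2.4), (9, 8, 7))
        vox_cc = geom.voxel_volume_cc
        for _ in range(20):
            vals = rng.uniform(0, 80, geom.shape)
            dose = grid_with(geom, vals)
            for x_cc in (0.01, 0.5, 3.0):
                # independent oracle: full sort, running volume
                doses = np.sort(vals.reshape(-1))[::-1]
                cum = np.cumsum(np.full(len(doses), vox_cc))
                oracle = doses[np.argmax(cum >= x_cc)]
                assert metric_d_cc(dose, full_mask(geom), x_cc) == oracle


class TestOtherMetrics:
    def test_d_pct_and_v_gy(self, small_geom):
        vals = np.full(small_geom.shape, 20.0)
        vals[:5] = 60.0
        dose = grid_with(small_geom, vals)
        mask = full_mask(small_geom)
        assert metric_d_pct(dose, mask, 50.0) == 60.0
        assert metric_d_pct(dose, mask, 100.0) == 20.0
        assert metric_v_gy(dose, mask, 30.0) == 50.0
        assert metric_v_gy(dose, mask, 61.0) == 0.0

    def test_metric_string_dispatch(self, small_geom):
        vals = np.full(small_geom.shape, 25.0)
        dose = grid_with(small_geom, vals)
        mask = full_mask(small_geom)
        assert evaluate_metric(dose, mask, "DMAX") == 25.0
        assert evaluate_metric(dose, mask, "DMEAN") == 25.0
        assert evaluate_metric(dose, mask, "D0.01CC") == 25.0
        assert evaluate_metric(dose, mask, "D2%") == 25.0
        assert evaluate_metric(dose, mask, "V20GY") == 100.0
        with pytest.raises(ParameterError):
            evaluate_metric(dose, mask, "DWEIRD")


class TestScorecard:
    def test_all_zero_dose_passes_with_full_margin(self, small_geom):
        dose = grid_with(small_geom, np.zeros(small_geom.shape))
        card = rd.evaluate_scorecard(
            dose, [full_mask(small_geom, "cord")],
            [rd.Constraint("cord", "DMAX", 45.0)])
        assert card.all_pass
        assert card.rows[0].margin == 45.0

    def test_exact_equality_passes(self, small_geom):
        dose = grid_with(small_geom, np.full(small_geom.shape, 45.0))
        card = rd.evaluate_scorecard(
            dose, [full_mask(small_geom, "cord")],
            [rd.Constraint("cord", "DMAX", 45.0)])
        assert card.rows[0].status == "PASS"

    def test_over_limit_fails_with_negative_margin(self, small_geom):
        dose = grid_with(small_geom, np.full(small_geom.shape, 50.0))
        card = rd.evaluate_scorecard(
            dose, [full_mask(small_geom, "cord")],
            [rd.Constraint("cord", "DMAX", 45.0)])
        assert card.rows[0].status == "FAIL"
        assert card.rows[0].margin == -5.0

    def test_scaling_up_never_turns_fail_into_pass(self, small_geom, rng):
        vals = rng.uniform(0, 60, small_geom.shape)
        mask = full_mask(small_geom, "cord")
        cons = [rd.Constraint("cord", "DMAX", 45.0),
                rd.Constraint("cord", "DMEAN", 25.0),
                rd.Constraint("cord", "D0.01CC", 40.0)]
        base = rd.evaluate_scorecard(grid_with(small_geom, vals), [mask], cons)
        scaled = rd.evaluate_scorecard(grid_with(small_geom, vals * 1.3), [mask], cons)
        for b, s in zip(base.rows, scaled.rows):
            if b.status == "FAIL":
                assert s.status == "FAIL"


class TestReport:
    def test_report_round_trip_and_scorecard_equality(self, tmp_path, small_geom):
        vals = np.full(small_geom.shape, 30.0)
        dose = grid_with(small_geom, vals)
        mask = full_mask(small_geom, "cord")
        card = rd.evaluate_scorecard(dose, [mask], [rd.Constraint("cord", "DMAX", 45.0)])
        accum = rd.AccumulationResult(summed_eqd2=dose, per_course_eqd2=[dose],
                                      provenance=[{"course_id": "c1"}])
        curves = [rd.compute_dvh(dose, mask, 0.5)]
        report = rd.render_report(accum, card, curves, {"case_id": "t"}, tmp_path)
        parsed = json.loads((tmp_path / "report.json").read_text())
        assert parsed == report
        assert parsed["scorecard"] == card.to_records()
        assert (tmp_path / "dvh.csv").exists()
        assert (tmp_path / "dvh.png").exists()
        assert (tmp_path / "report.md").exists()

    def test_no_constraints_notice(self, tmp_path, small_geom):
        dose = grid_with(small_geom, np.full(small_geom.shape, 30.0))
        mask = full_mask(small_geom, "cord")
        accum = rd.AccumulationResult(summed_eqd2=dose, per_course_eqd2=[dose],
                                      provenance=[])
        report = render_report(accum, None, [rd.compute_dvh(dose, mask, 0.5)],
                               None, tmp_path)
        assert "no constraints evaluated" in report["notices"]
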