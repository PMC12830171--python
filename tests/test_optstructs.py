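"""Nested isodose optimization structures: arithmetic, partition, limits."""

import numpy as np
import pytest

import redose as rd
from redose.errors import ParameterError
from redose.optstructs import export_structures


def uniform_case(geom, eqd2_value):
    summed = rd.DoseGrid(geom, np.full(geom.shape, float(eqd2_value)), rd.DoseKind.EQD2)
    oar = rd.StructureMask("OAR", geom, np.ones(geom.shape, bool))
    return summed, oar


SCHEME = rd.FractionationScheme(30)


class TestWorkedExampleArithmetic:
    """P = 57, R = 60, A = 60: the printed worked-example inputs."""

    def test_n5_thresholds_and_limits(self, small_geom):
        summed, oar = uniform_case(small_geom, 57.0)
        s = rd.generate(rd.OptStructParams(R=60, A=60, N=5), 57.0, summed, oar,
                        SCHEME, 3.0)
        assert s.d == pytest.approx(11.4, rel=1e-12)
        np.testing.assert_allclose([x.threshold for x in s.structures],
                                   [45.6, 34.2, 22.8, 11.4, 0.0], rtol=1e-9)
        np.testing.assert_allclose([x.eqd2_limit for x in s.structures],
                                   [3.0, 14.4, 25.8, 37.2, 48.6], rtol=1e-9)

    def test_n3_limits(self, small_geom):
        summed, oar = uniform_case(small_geom, 57.0)
        s = rd.generate(rd.OptStructParams(R=60, A=60, N=3), 57.0, summed, oar,
                        SCHEME, 3.0)
        np.testing.assert_allclose([x.threshold for x in s.structures],
                                   [38.0, 19.0, 0.0], rtol=1e-9)
        np.testing.assert_allclose([x.eqd2_limit for x in s.structures],
                                   [3.0, 22.0, 41.0], rtol=1e-9)

    def test_physical_limits_round_trip(self, small_geom):
        summed, oar = uniform_case(small_geom, 57.0)
        s = rd.generate(rd.OptStructParams(R=60, A=60, N=3), 57.0, summed, oar,
                        SCHEME, 3.0)
        for x in s.structures:
            back = rd.eqd2_forward(x.physical_limit, SCHEME.n_fractions, 3.0)
            assert back == pytest.approx(x.eqd2_limit, abs=1e-9)


class TestEmptyRule:
    def test_full_prescription_fits(self, small_geom):
        summed, oar = uniform_case(small_geom, 10.0)
        s = rd.generate(rd.OptStructParams(R=20, A=40), 10.0, summed, oar, SCHEME, 3.0)
        assert s.is_empty

    def test_equality_treated_as_empty(self, small_geom):
        summed, oar = uniform_case(small_geom, 20.0)
        s = rd.generate(rd.OptStructParams(R=20, A=40), 20.0, summed, oar, SCHEME, 3.0)
        assert s.is_empty

    def test_structure_count_rule_random_sweep(self, small_geom, rng):
        summed, oar = uniform_case(small_geom, 30.0)
        for _ in range(200):
            P, R = rng.uniform(0, 80, 2)
            A = rng.uniform(1, 80)
            N = int(rng.integers(1, 8))
            s = rd.generate(rd.OptStructParams(R=R, A=A, N=N), P, summed, oar,
                            SCHEME, 3.0)
            if P + R <= A:
                assert s.is_empty
            else:
                assert len(s.structures) == N

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            rd.OptStructParams(R=10, A=0)
        with pytest.raises(ParameterError):
            rd.OptStructParams(R=10, A=10, N=0)


class TestNearTargetDmax:
    def test_uniform_oar_gives_that_value(self, example_accum, example_bundle):
        P = rd.compute_near_target_dmax(
            example_accum.summed_eqd2, example_bundle.structures["OAR"],
            example_bundle.structures["PTV"], 20.0)
        assert P == pytest.approx(57.0, abs=0.01)

    def test_zero_dose_gives_zero(self, small_geom):
        summed = rd.DoseGrid(small_geom, np.zeros(small_geom.shape), rd.DoseKind.EQD2)
        oar = rd.StructureMask("o", small_geom, np.ones(small_geom.shape, bool))
        tgt = rd.StructureMask("t", small_geom, np.ones(small_geom.shape, bool))
        assert rd.compute_near_target_dmax(summed, oar, tgt, 5.0) == 0.0

    def test_hot_voxel_outside_near_region_ignored(self, small_geom):
        vals = np.full(small_geom.shape, 45.0)
        vals[9, 9, 5] = 62.0  # hot voxel far from the target
        summed = rd.DoseGrid(small_geom, vals, rd.DoseKind.EQD2)
        oar = rd.StructureMask("o", small_geom, np.ones(small_geom.shape, bool))
        tm = np.zeros(small_geom.shape, bool)
        tm[0, 0, 0] = True
        tgt = rd.StructureMask("t", small_geom, tm)
        assert rd.compute_near_target_dmax(summed, oar, tgt, 3.0) == pytest.approx(45.0)

    def test_disjoint_near_region_falls_back_with_warning(self, small_geom):
        vals = np.full(small_geom.shape, 30.0)
        summed = rd.DoseGrid(small_geom, vals, rd.DoseKind.EQD2)
        om = np.zeros(small_geom.shape, bool)
        om[0, 0, 0] = True
        tm = np.zeros(small_geom.shape, bool)
        tm[9, 9, 5] = True
        with pytest.warns(UserWarning, match="whole OAR"):
            P = rd.compute_near_target_dmax(
                summed, rd.StructureMask("o", small_geom, om),
                rd.StructureMask("t", small_geom, tm), 1.0)
        assert P == 30.0

    def test_empty_oar_rejected(self, small_geom):
        summed = rd.DoseGrid(small_geom, np.zeros(small_geom.shape), rd.DoseKind.EQD2)
        empty = rd.StructureMask("o", small_geom, np.zeros(small_geom.shape, bool))
        tgt = rd.StructureMask("t", small_geom, np.ones(small_geom.shape, bool))
        with pytest.raises(ParameterError):
            rd.compute_near_target_dmax(summed, empty, tgt, 5.0)


@pytest.fixture(scope="module")
def example_set(example_accum, example_bundle):
    P = rd.compute_near_target_dmax(
        example_accum.summed_eqd2, example_bundle.structures["OAR"],
        example_bundle.structures["PTV"], 20.0)
    return P, rd.generate(
        rd.OptStructParams(R=60, A=60, N=5), P, example_accum.summed_eqd2,
        example_bundle.structures["OAR"], SCHEME, 3.0)


class TestPartitionAndConservativeness:
    def test_masks_pairwise_disjoint(self, example_set):
        _, s = example_set
        total = np.zeros(s.structures[0].mask.geometry.shape, int)
        for x in s.structures:
            total += x.mask.mask
        assert total.max() <= 1

    def test_telescoping_against_threshold_oracle(self, example_set, example_accum, example_bundle):
        """Union of S_1..S_k equals OAR voxels at or above D_k, for every k."""
        _, s = example_set
        oar = example_bundle.structures["OAR"].mask
        eqd2 = example_accum.summed_eqd2.values
        union = np.zeros_like(oar)
        for x in s.structures:
            union |= x.mask.mask
            oracle = oar & (eqd2 >= x.threshold)
            np.testing.assert_array_equal(union, oracle)

    def test_rest_completes_the_oar(self, example_set, example_bundle):
        _, s = example_set
        union = np.zeros_like(example_bundle.structures["OAR"].mask)
        for x in s.structures:
            union |= x.mask.mask
        union |= s.rest_mask.mask
        np.testing.assert_array_equal(union, example_bundle.structures["OAR"].mask)

    def test_assumed_prior_bounds_actual_dose(self, example_set, example_accum):
        """Every shell voxel's assumed prior dose >= its actual prior EQD2."""
        _, s = example_set
        eqd2 = example_accum.summed_eqd2.values
        for x in s.structures:
            if x.mask.mask.any():
                assert eqd2[x.mask.mask].max() <= x.assumed_prior + 1e-9

    def test_budget_consistency(self, example_set):
        _, s = example_set
        for x in s.structures:
            assert x.assumed_prior + x.eqd2_limit == pytest.approx(60.0, abs=1e-12)

    def test_lowest_threshold_is_A_minus_R(self, example_set):
        # D_N = P - N*d = A - R algebraically (here 0)
        _, s = example_set
        assert s.structures[-1].threshold == pytest.approx(0.0, abs=1e-9)

    def test_doubling_n_refines_thresholds(self, example_accum, example_bundle):
        P = 57.0
        args = (example_accum.summed_eqd2, example_bundle.structures["OAR"], SCHEME, 3.0)
        t3 = {round(x.threshold, 9) for x in rd.generate(
            rd.OptStructParams(R=60, A=60, N=3), P, *args).structures}
        t6 = {round(x.threshold, 9) for x in rd.generate(
            rd.OptStructParams(R=60, A=60, N=6), P, *args).structures}
        assert t3 <= t6


class TestExport:
    def test_names_and_count(self, example_set):
        _, s = example_set
        masks = export_structures(s, "OAR")
        names = [m.name for m in masks]
        assert names == ["OAR_S1", "OAR_S2", "OAR_S3", "OAR_S4", "OAR_S5", "OAR_rest"]
        assert len(set(names)) == len(names)
        assert masks[0].limit_physical == pytest.approx(s.structures[0].physical_limit)

    def test_empty_set_exports_nothing(self, small_geom):
        summed, oar = uniform_case(small_geom, 5.0)
        s = rd.generate(rd.OptStructParams(R=10, A=40), 5.0, summed, oar, SCHEME, 3.0)
        with pytest.warns(UserWarning, match="empty"):
            assert export_structures(s, "OAR") == []
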