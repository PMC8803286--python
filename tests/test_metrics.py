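"""ROI construction, DVH metrics, dose statistics, robustness report."""

import numpy as np
import pytest

from expander_sim import (DoseGrid, DVHMetricSpec, StructureSet, build_report,
                          build_roi, dose_difference_map, dvh_value,
                          point_dose_stats, port_slice_extent, restrict_oar,
                          run_reference, v100_rx, Shift)
from expander_sim.errors import GeometryError, StatisticsError


def sphere_structures(radius=30.0, shape=(64, 64, 64), h=2.5, ptv="all"):
    origin = -(np.array(shape) - 1) / 2 * h
    coords = [origin[i] + h * np.arange(shape[i]) for i in range(3)]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    implant = gx ** 2 + gy ** 2 + gz ** 2 <= radius ** 2
    if ptv == "all":
        ptv_mask = np.ones(shape, bool)
    else:
        ptv_mask = gx <= 0  # half-space PTV truncates the shell
    return StructureSet({"implant": implant, "ptv": ptv_mask},
                        (h, h, h), origin)


def dose_on(mask_set, values):
    return DoseGrid(values, mask_set.spacing, mask_set.origin)


class TestBuildROI:
    def test_shell_volume_matches_analytic(self):
        st = sphere_structures(radius=30.0)
        roi = build_roi(st, None, expansion_mm=5.0)
        analytic = 4 / 3 * np.pi * (35.0 ** 3 - 30.0 ** 3) / 2.5 ** 3
        assert abs(roi.n_voxels - analytic) / analytic < 0.07

    def test_truncated_by_ptv_boundary(self):
        full = build_roi(sphere_structures(), None)
        cut = build_roi(sphere_structures(ptv="half"), None)
        assert 0 < cut.n_voxels < full.n_voxels
        assert cut.provenance["ptv_truncated"]

    def test_zero_expansion_is_empty_with_warning(self):
        with pytest.warns(UserWarning):
            roi = build_roi(sphere_structures(), None, expansion_mm=0.0)
        assert roi.n_voxels == 0

    def test_roi_excludes_implant_and_respects_slices(self):
        st = sphere_structures()
        roi = build_roi(st, (30, 33))
        assert not (roi.mask & st["implant"]).any()
        zs = np.flatnonzero(roi.mask.any(axis=(0, 1)))
        assert zs.min() >= 30 and zs.max() <= 33

    def test_port_slice_extent_grows_with_migration(self, small_phantom):
        _, structures = small_phantom
        lo0, hi0 = port_slice_extent(structures)
        lo1, hi1 = port_slice_extent(structures, [Shift(0, 0, -10.0),
                                                  Shift(0, 0, 12.5)])
        assert lo1 <= lo0 and hi1 >= hi0
        assert (hi1 - hi0) == 5 and (lo0 - lo1) == 4


class TestDoseDifferenceMap:
    def test_identical_doses_give_zero(self):
        st = sphere_structures(shape=(16, 16, 16))
        d = dose_on(st, np.random.default_rng(0).uniform(0, 60, (16, 16, 16)))
        assert np.all(dose_difference_map(d, d, 50.0) == 0)

    def test_uniform_offset_scales_with_rx(self):
        st = sphere_structures(shape=(8, 8, 8))
        a = dose_on(st, np.full((8, 8, 8), 30.0))
        b = dose_on(st, np.full((8, 8, 8), 25.0))
        np.testing.assert_allclose(dose_difference_map(a, b, 50.0), 10.0)

    def test_antisymmetric(self, rng):
        st = sphere_structures(shape=(12, 12, 12))
        a = dose_on(st, rng.uniform(0, 60, (12, 12, 12)))
        b = dose_on(st, rng.uniform(0, 60, (12, 12, 12)))
        np.testing.assert_allclose(dose_difference_map(a, b, 50.0),
                                   -dose_difference_map(b, a, 50.0))

    def test_shape_mismatch_rejected(self):
        a = dose_on(sphere_structures(shape=(8, 8, 8)), np.zeros((8, 8, 8)))
        b = dose_on(sphere_structures(shape=(9, 9, 9)), np.zeros((9, 9, 9)))
        with pytest.raises(GeometryError):
            dose_difference_map(a, b, 50.0)


class TestPointDoseStats:
    def test_constant_map(self):
        mask = np.ones((4, 4, 4), bool)
        s = point_dose_stats(np.full((4, 4, 4), 3.5), mask)
        assert (s.mean, s.iqr, s.p1, s.p99) == (3.5, 0.0, 3.5, 3.5)

    def test_linear_interpolation_percentiles(self):
        vals = np.arange(1, 101, dtype=float)
        diff = np.zeros((10, 10, 1))
        diff[:, :, 0] = vals.reshape(10, 10)
        s = point_dose_stats(diff, np.ones_like(diff, bool))
        assert s.p1 == pytest.approx(1.99)
        assert s.p99 == pytest.approx(99.01)
        assert s.iqr == pytest.approx(np.percentile(vals, 75) - np.percentile(vals, 25))

    def test_invariant_under_permutation(self, rng):
        diff = rng.normal(0, 2, (6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.5
        s1 = point_dose_stats(diff, mask)
        flat = diff[mask]
        shuffled = np.zeros_like(diff)
        shuffled[mask] = rng.permutation(flat)
        s2 = point_dose_stats(shuffled, mask)
        # order statistics are exact; the mean only up to summation order
        assert (s2.iqr, s2.p1, s2.p99) == (s1.iqr, s1.p1, s1.p99)
        assert s2.mean == pytest.approx(s1.mean, rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(StatisticsError):
            point_dose_stats(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool))


def dvh_oracle(vals, spec, rx):
    """Exhaustive counting oracle for V_x / D_x / mean."""
    if spec.kind == "mean":
        return sum(vals) / len(vals)
    if spec.kind == "V":
        return 100.0 * sum(1 for v in vals if v >= spec.threshold) / len(vals)
    srt = sorted(vals, reverse=True)
    k = max(1, int(np.ceil(spec.threshold / 100.0 * len(srt))))
    return srt[min(k, len(srt)) - 1]


class TestDVH:
    def test_uniform_dose_full_coverage(self):
        st = sphere_structures(shape=(8, 8, 8))
        d = dose_on(st, np.full((8, 8, 8), 50.0))
        assert v100_rx(d, np.ones((8, 8, 8), bool), 50.0) == 100.0

    def test_bimodal_dose_analytic(self):
        st = sphere_structures(shape=(8, 8, 8))
        vals = np.full((8, 8, 8), 40.0)
        vals[:4] = 60.0
        d = dose_on(st, vals)
        mask = np.ones((8, 8, 8), bool)
        assert dvh_value(d, mask, DVHMetricSpec("V", 50.0), 50.0) == 50.0
        assert dvh_value(d, mask, DVHMetricSpec("D", 90.0), 50.0) == 40.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_grids_match_counting_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        shape = (9, 7, 5)
        st_set = sphere_structures(shape=shape)
        d = dose_on(st_set, rng.uniform(0, 70, shape))
        mask = rng.random(shape) < 0.6
        vals = list(d.values[mask])
        for spec in (DVHMetricSpec("V", 20.0), DVHMetricSpec("V", 50.0),
                     DVHMetricSpec("D", 90.0), DVHMetricSpec("D", 2.0)):
            assert dvh_value(d, mask, spec, 50.0) == dvh_oracle(vals, spec, 50.0)
        # the mean is exact only up to float summation order
        assert dvh_value(d, mask, DVHMetricSpec("mean"), 50.0) == pytest.approx(
            dvh_oracle(vals, DVHMetricSpec("mean"), 50.0), rel=1e-12)

    def test_v_non_increasing_and_consistent_with_d(self, rng):
        shape = (10, 10, 10)
        st_set = sphere_structures(shape=shape)
        d = dose_on(st_set, rng.uniform(0, 70, shape))
        mask = np.ones(shape, bool)
        xs = np.linspace(0, 70, 15)
        vs = [dvh_value(d, mask, DVHMetricSpec("V", x), 50.0) for x in xs]
        assert np.all(np.diff(vs) <= 0)
        for pct in (10.0, 50.0, 90.0):
            dx = dvh_value(d, mask, DVHMetricSpec("D", pct), 50.0)
            assert dvh_value(d, mask, DVHMetricSpec("V", dx), 50.0) >= pct

    def test_empty_mask_rejected(self):
        st_set = sphere_structures(shape=(4, 4, 4))
        d = dose_on(st_set, np.zeros((4, 4, 4)))
        with pytest.raises(StatisticsError):
            dvh_value(d, np.zeros((4, 4, 4), bool), DVHMetricSpec("mean"), 50.0)


class TestRestrictOAR:
    def test_full_span_roi_keeps_oar(self, rng):
        oar = rng.random((6, 6, 6)) < 0.5
        roi = np.ones((6, 6, 6), bool)
        np.testing.assert_array_equal(restrict_oar(oar, roi), oar)

    def test_empty_roi_empties_oar(self):
        oar = np.ones((6, 6, 6), bool)
        assert restrict_oar(oar, np.zeros((6, 6, 6), bool)).sum() == 0

    def test_per_slice_counting_oracle(self, rng):
        oar = rng.random((6, 6, 8)) < 0.5
        roi = np.zeros((6, 6, 8), bool)
        roi[2, 3, [1, 4]] = True
        restricted = restrict_oar(oar, roi)
        for k in range(8):
            expected = oar[:, :, k].sum() if k in (1, 4) else 0
            assert restricted[:, :, k].sum() == expected


class TestReport:
    def test_reference_only_gives_exact_zero_deltas(self, small_phantom,
                                                    small_tangential):
        grid, structures = small_phantom
        plan, _ = small_tangential
        ref = run_reference(grid, structures, plan)
        roi = build_roi(structures, port_slice_extent(structures))
        rep = build_report(ref, [run_reference(grid, structures, plan)],
                           structures, roi, 50.0)
        row = rep.rows[0]
        assert row["delta_v100rx_roi_pct"] == 0.0
        assert row["delta_v20gy_lung_pct"] == 0.0
        assert row["delta_v5gy_heart_pct"] == 0.0
        assert row["diff_iqr_pct"] == 0.0 and row["diff_p99_pct"] == 0.0

    def test_report_fields_complete_and_reproducible(self, small_phantom,
                                                     small_tangential):
        grid, structures = small_phantom
        plan, _ = small_tangential
        ref = run_reference(grid, structures, plan)
        roi = build_roi(structures, port_slice_extent(structures))
        reps = [build_report(ref, [ref], structures, roi, 50.0)
                for _ in range(2)]
        assert reps[0].rows == reps[1].rows
        assert reps[0].reference_values == reps[1].reference_values
        df = reps[0].to_dataframe()
        assert {"technique", "scenario", "delta_v100rx_roi_pct",
                "diff_p1_pct"} <= set(df.columns)
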