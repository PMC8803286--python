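"""Dose engine primitives and technique plan builders."""

import numpy as np
import pytest

from expander_sim import (Aperture, Beam, DensityGrid, PlanBuildConfig,
                          compute_beam_dose, compute_plan_dose, make_arc_plan,
                          make_helical_plan, make_tangential_plan,
                          normalize_plan, normalize_plan_with_dose,
                          radiological_path)
from expander_sim.dosecalc import MU_WATER_PER_CM, _d_hottest
from expander_sim.errors import NormalizationError, PlanError
from expander_sim.grids import StructureSet

from conftest import small_phantom_config


def water_grid(shape=(64, 64, 32), h=2.5, rho=1.0):
    origin = -(np.array(shape) - 1) / 2 * h
    return DensityGrid(np.full(shape, rho), (h, h, h), origin)


def anterior_beam(aperture=None, weight=1.0):
    ap = aperture or Aperture(rect=(-60, 60, -30, 30))
    return Beam(0.0, (0.0, 0.0, 0.0), ap, weight=weight)


class TestRadiologicalPath:
    def test_uniform_segment_analytic(self):
        grid = water_grid()
        # 100 mm fully inside a unit-density grid -> 10 g/cm^2
        assert radiological_path(grid, (0, 50, 0), (0, -50, 0)) == pytest.approx(10.0, rel=1e-9)

    def test_symmetric_in_endpoints(self):
        grid = water_grid()
        a, b = (-30.0, 40.0, -10.0), (25.0, -35.0, 20.0)
        assert radiological_path(grid, a, b) == pytest.approx(
            radiological_path(grid, b, a), rel=1e-12)

    def test_outside_grid_is_zero(self):
        grid = water_grid()
        assert radiological_path(grid, (500, 0, 0), (500, 100, 0)) == 0.0

    def test_additive_over_subsegments(self):
        grid = water_grid()
        a, b = np.array([-40, 60, -20.0]), np.array([30, -50, 25.0])
        whole = radiological_path(grid, a, b)
        m = a + 0.37 * (b - a)  # interior point of the segment
        parts = radiological_path(grid, a, m) + radiological_path(grid, m, b)
        assert whole == pytest.approx(parts, rel=1e-9)

    def test_matches_dense_quadrature_on_heterogeneous_grid(self, rng):
        shape = (24, 24, 16)
        h = 3.0
        origin = -(np.array(shape) - 1) / 2 * h
        vals = rng.uniform(0.2, 3.0, size=shape)
        grid = DensityGrid(vals, (h, h, h), origin)
        lo = origin - h / 2
        for _ in range(10):
            p0 = rng.uniform(-60, 60, 3)
            p1 = rng.uniform(-60, 60, 3)
            if np.linalg.norm(p1 - p0) < 10:
                continue
            exact = radiological_path(grid, p0, p1)
            # 10,000-point midpoint quadrature oracle
            ts = (np.arange(10000) + 0.5) / 10000
            pts = p0 + ts[:, None] * (p1 - p0)
            idx = np.floor((pts - lo) / h).astype(int)
            inside = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
            rho = np.zeros(len(ts))
            rho[inside] = vals[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
            quad = rho.mean() * np.linalg.norm(p1 - p0) / 10
            assert exact == pytest.approx(quad, rel=5e-3)

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError):
            radiological_path(water_grid(), (0, 0, 0), (0, 0, 0))


class TestBeamDose:
    def test_central_axis_exponential_attenuation(self):
        grid = water_grid()
        dose = compute_beam_dose(grid, anterior_beam(), blur=False)
        ix = np.argmin(np.abs(grid.axis_coords(0)))
        iz = np.argmin(np.abs(grid.axis_coords(2)))
        ys = grid.axis_coords(1)
        col = dose.values[ix, :, iz]
        i1, i2 = 50, 20  # shallower, deeper (beam travels -y)
        c1 = col[i1] * ((1000 - ys[i1]) / 1000) ** 2  # strip inverse-square
        c2 = col[i2] * ((1000 - ys[i2]) / 1000) ** 2
        expected = np.exp(-MU_WATER_PER_CM * (ys[i1] - ys[i2]) / 10)
        assert c2 / c1 == pytest.approx(expected, rel=1e-3)

    def test_dense_slab_casts_exponential_shadow(self):
        grid = water_grid()
        vals = grid.values.copy()
        ys = grid.axis_coords(1)
        vals[:, (ys > 20) & (ys <= 30), :] = 8.0  # 10-mm slab of density 8
        slab_grid = DensityGrid(vals, grid.spacing, grid.origin)
        d0 = compute_beam_dose(grid, anterior_beam(), blur=False)
        d1 = compute_beam_dose(slab_grid, anterior_beam(), blur=False)
        ix = np.argmin(np.abs(grid.axis_coords(0)))
        iz = np.argmin(np.abs(grid.axis_coords(2)))
        iy = np.argmin(np.abs(ys - 10.0))  # immediately distal of the slab
        expected = np.exp(-MU_WATER_PER_CM * (8.0 - 1.0) * 1.0)
        assert d1.values[ix, iy, iz] / d0.values[ix, iy, iz] == pytest.approx(
            expected, rel=5e-3)

    def test_far_outside_aperture_below_one_percent(self):
        grid = water_grid()
        ap = Aperture(rect=(-30, 30, -30, 30))
        dose = compute_beam_dose(grid, anterior_beam(ap), blur=True)
        xs = grid.axis_coords(0)
        ix0 = np.argmin(np.abs(xs))
        iy = np.argmin(np.abs(grid.axis_coords(1)))
        iz = np.argmin(np.abs(grid.axis_coords(2)))
        cax = dose.values[ix0, iy, iz]
        beyond = np.abs(xs) > 30 + 3 * 5.0  # aperture edge + 3 sigma
        assert dose.values[beyond, iy, iz].max() < 0.01 * cax

    def test_linear_in_weight(self):
        grid = water_grid(shape=(32, 32, 16))
        d1 = compute_beam_dose(grid, anterior_beam(weight=1.0), blur=False)
        d2 = compute_beam_dose(grid, anterior_beam(weight=2.0), blur=False)
        np.testing.assert_array_equal(d2.values, 2.0 * d1.values)

    def test_zero_aperture_with_weight_raises(self):
        with pytest.raises(PlanError):
            Beam(0.0, (0, 0, 0), Aperture(mask=np.zeros((3, 3), bool)),
                 weight=1.0)

    def test_shadow_monotonicity(self):
        """Adding density on a ray never increases pre-blur distal dose."""
        grid = water_grid(shape=(32, 48, 16))
        vals = grid.values.copy()
        iy_block = 30
        vals[14:18, iy_block, :] = 5.0
        denser = DensityGrid(vals, grid.spacing, grid.origin)
        d0 = compute_beam_dose(grid, anterior_beam(), blur=False)
        d1 = compute_beam_dose(denser, anterior_beam(), blur=False)
        distal = np.s_[14:18, :iy_block - 2, :]  # beam travels toward -y
        assert np.all(d1.values[distal] <= d0.values[distal] + 1e-12)


class TestPlanDose:
    def test_superposition_of_beams(self, small_phantom):
        grid, structures = small_phantom
        plan = make_tangential_plan(structures)
        total = compute_plan_dose(grid, plan, blur=False)
        summed = sum(compute_beam_dose(grid, b, blur=False).values
                     for b in plan.beams)
        np.testing.assert_allclose(total.values, summed, rtol=1e-12, atol=1e-15)


class TestTangentialPlan:
    def test_parallel_opposed_geometry(self, small_phantom):
        _, structures = small_phantom
        plan = make_tangential_plan(structures)
        g1, g2 = (b.gantry_deg for b in plan.beams)
        assert abs(g1 - g2) % 360 == 180
        iso1, iso2 = (np.asarray(b.isocenter) for b in plan.beams)
        np.testing.assert_allclose(iso1, iso2)

    def test_posterior_half_block_edges_coincide(self, small_phantom):
        _, structures = small_phantom
        plan = make_tangential_plan(structures)
        for b in plan.beams:
            assert b.half_block_u == 0.0
            u0, u1, _, _ = b.aperture.rect
            assert u0 == 0.0 or u1 == 0.0  # blocked side exactly at u = 0

    def test_every_ptv_voxel_inside_both_apertures(self, small_phantom):
        _, structures = small_phantom
        plan = make_tangential_plan(structures)
        pts = (structures.origin
               + np.argwhere(structures["ptv"]) * structures.spacing)
        for b in plan.beams:
            u, v, _, _ = b.bev_coords(pts)
            assert b.aperture.contains(u, v).all()

    def test_empty_ptv_raises(self, small_phantom):
        _, structures = small_phantom
        empty = StructureSet({"ptv": np.zeros(structures.shape, bool)},
                             structures.spacing, structures.origin)
        with pytest.raises(PlanError):
            make_tangential_plan(empty)


class TestArcPlan:
    def test_span_is_230_degrees(self, small_phantom):
        _, structures = small_phantom
        plan = make_arc_plan(structures)
        angles = [b.gantry_deg for b in plan.beams]
        assert max(angles) - min(angles) == pytest.approx(230.0)
        assert len(plan.beams) == 47

    def test_isocenter_at_ptv_centroid(self, small_phantom):
        _, structures = small_phantom
        plan = make_arc_plan(structures)
        pts = (structures.origin
               + np.argwhere(structures["ptv"]) * structures.spacing)
        np.testing.assert_allclose(plan.beams[0].isocenter, pts.mean(axis=0),
                                   atol=max(structures.spacing))

    def test_mirrored_laterality_mirrors_gantry_angles(self, small_phantom):
        _, structures = small_phantom
        left = make_arc_plan(structures, PlanBuildConfig(laterality="left"))
        right = make_arc_plan(structures, PlanBuildConfig(laterality="right"))
        for bl, br in zip(left.beams, right.beams):
            assert (bl.gantry_deg + br.gantry_deg) % 360 == pytest.approx(0.0)


class TestHelicalPlan:
    def test_angles_cover_full_rotation_uniformly(self, small_phantom):
        _, structures = small_phantom
        plan = make_helical_plan(structures)
        angles = sorted({b.gantry_deg for b in plan.beams})
        diffs = np.diff(angles)
        assert angles[0] == 0.0 and angles[-1] < 360.0
        np.testing.assert_allclose(diffs, diffs[0])

    def test_fan_windows_cover_ptv_z_range(self, small_phantom):
        _, structures = small_phantom
        plan = make_helical_plan(structures)
        meta = plan.meta_dict
        half = meta["fan_width"] / 2
        lo = min(meta["stations"]) - half
        hi = max(meta["stations"]) + half
        pts = (structures.origin
               + np.argwhere(structures["ptv"]) * structures.spacing)
        assert lo <= pts[:, 2].min() and hi >= pts[:, 2].max()

    def test_apertures_conformal_to_ptv_projection(self, small_phantom):
        """No aperture opening farther than margin + raster cell from the PTV."""
        _, structures = small_phantom
        config = PlanBuildConfig()
        plan = make_helical_plan(structures, config)
        pts = (structures.origin
               + np.argwhere(structures["ptv"]) * structures.spacing)
        for b in plan.beams[:: max(1, len(plan.beams) // 8)]:
            ap = b.aperture
            u, v, _, _ = b.bev_coords(pts)
            iu, iv = np.nonzero(ap.mask)
            cu = ap.mask_u0 + ap.mask_cell * iu
            cv = ap.mask_v0 + ap.mask_cell * iv
            d2 = ((cu[:, None] - u[None, :]) ** 2
                  + (cv[:, None] - v[None, :]) ** 2).min(axis=1)
            limit = config.aperture_margin + 2.0 * config.bev_cell
            assert np.sqrt(d2.max()) <= limit


class TestNormalizePlan:
    def test_ptv_d90_equals_prescription(self, small_phantom, small_tangential):
        grid, structures = small_phantom
        _, dose = small_tangential
        vals = dose.values[structures["ptv"]]
        assert _d_hottest(vals, 90.0) == pytest.approx(50.0, abs=0.05)

    def test_doubling_weights_halves_factor(self, small_phantom):
        grid, structures = small_phantom
        plan = make_tangential_plan(structures)
        n1 = normalize_plan(plan, grid, structures)
        n2 = normalize_plan(plan.with_weights_scaled(2.0), grid, structures)
        f1 = n1.meta_dict["normalization_factor"]
        f2 = n2.meta_dict["normalization_factor"]
        assert f2 == pytest.approx(f1 / 2, rel=1e-9)

    def test_relative_dvh_invariant_under_input_scaling(self, small_phantom):
        grid, structures = small_phantom
        plan = make_tangential_plan(structures)
        _, d1 = normalize_plan_with_dose(plan, grid, structures)
        _, d2 = normalize_plan_with_dose(plan.with_weights_scaled(3.0), grid,
                                         structures)
        np.testing.assert_allclose(d1.values, d2.values, rtol=1e-9)

    def test_zero_total_weight_rejected(self, small_phantom):
        grid, structures = small_phantom
        plan = make_tangential_plan(structures)
        with pytest.raises(PlanError):
            plan.with_weights_scaled(0.0)

    def test_zero_ptv_dose_raises(self, small_phantom):
        # PTV far outside every aperture receives no dose -> unnormalizable
        grid, structures = small_phantom
        plan = make_tangential_plan(structures)
        shifted = StructureSet(dict(structures.masks), structures.spacing,
                               structures.origin)
        far = np.zeros(structures.shape, bool)
        far[0, 0, 0] = True
        shifted.masks["ptv"] = far
        with pytest.raises(NormalizationError):
            normalize_plan(plan, grid, shifted)
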