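"""Synthetic flow generator: geometry, vortex models, oracle, calibration."""

import math
from dataclasses import replace

import numpy as np
import pytest

from vortexhab import (
    BedProfile,
    CalibrationError,
    ContractError,
    EmptyWettedAreaError,
    ScenarioSpec,
    VortexSpec,
    analytic_vorticity,
    build_section_geometry,
    calibrate_circulation,
    evaluate_velocity,
    generate_scenario,
)
from vortexhab.vorticity import compute_cell_vorticity, mean_vorticity


def _single_vortex_spec(bed, vortices, ws=1.0, ny=20, nz=20, **kw):
    return ScenarioSpec(
        label="spawning", bed=bed, vortices=tuple(vortices),
        water_surface=ws, ny=ny, nz=nz, **kw,
    )


class TestGeometry:
    def test_flat_rectangle_is_fully_wet(self):
        g = build_section_geometry(BedProfile("flat", 1.0, 1.0), 10, 10, 1.0)
        assert g.n_wet == 100
        assert g.wetted_area == pytest.approx(1.0)

    def test_vee_half_depth_matches_triangle_area(self):
        bed = BedProfile("vee", width=2.0, max_depth=1.0)
        g = build_section_geometry(bed, 200, 200, 0.5)
        exact = bed.wetted_area_analytic(0.5)
        assert exact == pytest.approx(0.5 * 1.0 * 0.5)  # 1/2 * top width * depth
        # discretization error bounded by one cell layer along the bed
        assert g.wetted_area == pytest.approx(exact, rel=0.02)

    def test_compound_area_matches_piecewise_parts(self):
        bed = BedProfile("compound", width=30.0, max_depth=2.2)
        ws = 1.8
        b = bed.berm_fraction * bed.width
        t = bed.transition_fraction * bed.width
        hb = bed.berm_height_fraction * bed.max_depth
        exact = (
            (bed.width - 2 * (b + t)) * ws      # main-channel rectangle
            + 2 * (t * ws - t * hb / 2)          # side-slope trapezoids
            + 2 * b * (ws - hb)                  # berm rectangles
        )
        assert bed.wetted_area_analytic(ws) == pytest.approx(exact)
        g = build_section_geometry(bed, 300, 300, ws)
        assert g.wetted_area == pytest.approx(exact, rel=0.01)

    def test_surface_below_invert_raises(self):
        with pytest.raises(EmptyWettedAreaError):
            build_section_geometry(BedProfile("flat", 1.0, 1.0), 8, 8, 0.0)


class TestVelocityField:
    def test_pure_base_flow_is_uniform(self, unit_grid):
        spec = _single_vortex_spec(
            BedProfile("flat", 1.0, 1.0), [], ny=10, nz=10,
            base_velocity=(0.5, 0.0),
        )
        g = evaluate_velocity(spec, unit_grid)
        assert np.allclose(g.v_y[g.wet], 0.5)
        assert np.allclose(g.v_z[g.wet], 0.0)

    def test_lamb_oseen_tangential_speed_at_core_radius(self):
        bed = BedProfile("flat", 2.0, 2.0)
        g0 = build_section_geometry(bed, 40, 40, 2.0)
        yc, zc = float(g0.y[20]), float(g0.z[20])  # center on an exact cell center
        vortex = VortexSpec(center=(yc, zc), circulation=1.0, core_radius=0.5)
        spec = _single_vortex_spec(bed, [vortex], ws=2.0, ny=40, nz=40)
        g = evaluate_velocity(spec, g0)
        # probe on the y-axis through the center, at r = r_c = 0.5 (10 cells right)
        expected = (1.0 / (2 * math.pi * 0.5)) * (1 - math.exp(-1))
        assert g.v_z[20, 30] == pytest.approx(expected, rel=1e-9)
        assert g.v_y[20, 30] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_sign_vortex_pair_leaves_symmetric_component(self):
        # probe midway between a +Gamma / -Gamma pair: the antisymmetric v_y
        # contributions cancel, the symmetric v_z contributions double
        bed = BedProfile("flat", 2.0, 2.0)
        base_grid = build_section_geometry(bed, 40, 40, 2.0)
        yp, zp = float(base_grid.y[20]), float(base_grid.z[20])  # an exact cell center
        v_plus = VortexSpec(center=(yp - 0.3, zp), circulation=1.0, core_radius=0.3)
        v_minus = VortexSpec(center=(yp + 0.3, zp), circulation=-1.0, core_radius=0.3)

        def probe(vortices, base):
            spec = _single_vortex_spec(
                bed, vortices, ws=2.0, ny=40, nz=40, base_velocity=base
            )
            g = evaluate_velocity(spec, build_section_geometry(bed, 40, 40, 2.0))
            return g.v_y[20, 20], g.v_z[20, 20]

        vy_pair, vz_pair = probe([v_plus, v_minus], base=(0.25, 0.0))
        vy_one, vz_one = probe([v_plus], base=(0.0, 0.0))
        assert vy_pair == pytest.approx(0.25, abs=1e-12)
        assert vz_pair == pytest.approx(2 * vz_one, rel=1e-9)

    def test_dry_cells_never_acquire_velocity(self):
        bed = BedProfile("vee", width=2.0, max_depth=1.0)
        spec = ScenarioSpec(
            label="nonspawning", bed=bed,
            vortices=(VortexSpec(center=(1.0, 0.5), circulation=1.0, core_radius=0.3),),
            base_velocity=(0.4, 0.1), background_shear=0.1, noise_sd=0.05,
            water_surface=1.0, ny=20, nz=20, seed=3,
        )
        g = evaluate_velocity(spec, build_section_geometry(bed, 20, 20, 1.0))
        assert np.all(g.v_y[~g.wet] == 0.0)
        assert np.all(g.v_z[~g.wet] == 0.0)

    def test_same_seed_reproduces_field_bit_for_bit(self):
        spec = generate_scenario("spawning", {"noise_sd": 0.05}, seed=11)
        grids = []
        for _ in range(2):
            g = build_section_geometry(spec.bed, spec.ny, spec.nz, spec.water_surface)
            grids.append(evaluate_velocity(spec, g))
        assert np.array_equal(grids[0].v_y, grids[1].v_y)
        assert np.array_equal(grids[0].v_z, grids[1].v_z)


class TestAnalyticVorticity:
    def test_lamb_oseen_peak_at_center(self):
        bed = BedProfile("flat", 2.0, 2.0)
        vortex = VortexSpec(center=(1.0, 1.0), circulation=1.0, core_radius=0.5)
        spec = _single_vortex_spec(bed, [vortex], ws=2.0)
        assert analytic_vorticity(spec, 1.0, 1.0) == pytest.approx(
            1.0 / (math.pi * 0.25), rel=1e-12
        )

    def test_pure_base_flow_is_irrotational(self):
        spec = _single_vortex_spec(
            BedProfile("flat", 1.0, 1.0), [], base_velocity=(0.7, 0.2)
        )
        y = np.linspace(0.1, 0.9, 7)
        assert np.allclose(analytic_vorticity(spec, y, y), 0.0)

    def test_rankine_exterior_is_irrotational(self):
        bed = BedProfile("flat", 2.0, 2.0)
        vortex = VortexSpec(
            center=(1.0, 1.0), circulation=1.0, core_radius=0.3, model="rankine"
        )
        spec = _single_vortex_spec(bed, [vortex], ws=2.0)
        assert analytic_vorticity(spec, 1.8, 1.0) == 0.0
        assert analytic_vorticity(spec, 1.0, 1.1) == pytest.approx(
            1.0 / (math.pi * 0.09)
        )

    def test_noise_violates_oracle_contract(self):
        spec = _single_vortex_spec(
            BedProfile("flat", 1.0, 1.0), [], noise_sd=0.01
        )
        with pytest.raises(ContractError):
            analytic_vorticity(spec, 0.5, 0.5)

    def test_two_vortex_curl_is_superposition(self):
        bed = BedProfile("flat", 2.0, 2.0)
        v1 = VortexSpec(center=(0.8, 1.0), circulation=0.7, core_radius=0.3)
        v2 = VortexSpec(center=(1.3, 0.8), circulation=1.1, core_radius=0.4)
        both = _single_vortex_spec(bed, [v1, v2], ws=2.0)
        one = _single_vortex_spec(bed, [v1], ws=2.0)
        two = _single_vortex_spec(bed, [v2], ws=2.0)
        y = np.linspace(0.05, 1.95, 23)
        z = np.linspace(0.05, 1.95, 23)
        total = analytic_vorticity(both, y, z)
        assert np.allclose(
            total, analytic_vorticity(one, y, z) + analytic_vorticity(two, y, z),
            rtol=1e-12,
        )

    def test_discrete_curl_converges_to_oracle_at_first_order(self):
        bed = BedProfile("flat", 1.0, 1.0)
        vortex = VortexSpec(center=(0.5, 0.5), circulation=1.0, core_radius=0.2)

        def max_error(n):
            spec = _single_vortex_spec(bed, [vortex], ny=n, nz=n)
            g = evaluate_velocity(spec, build_section_geometry(bed, n, n, 1.0))
            f = compute_cell_vorticity(g)
            yy, zz = g.meshgrid()
            return float(np.max(np.abs(f.omega - np.abs(analytic_vorticity(spec, yy, zz)))))

        errors = [max_error(n) for n in (16, 32, 64)]
        orders = [math.log2(errors[i] / errors[i + 1]) for i in range(2)]
        assert min(orders) >= 1.0


class TestScenarios:
    def test_nonspawning_mean_sits_at_baseline(self):
        spec = generate_scenario("nonspawning", seed=5)
        g = evaluate_velocity(
            spec, build_section_geometry(spec.bed, spec.ny, spec.nz, spec.water_surface)
        )
        mean = mean_vorticity(compute_cell_vorticity(g), g.wet)
        assert 0.08 <= mean <= 0.12

    def test_spawning_mean_lies_in_natural_interval(self):
        spec = generate_scenario("spawning", seed=5)
        g = evaluate_velocity(
            spec, build_section_geometry(spec.bed, spec.ny, spec.nz, spec.water_surface)
        )
        mean = mean_vorticity(compute_cell_vorticity(g), g.wet)
        assert 0.17 <= mean <= 0.35

    def test_spawning_vortices_sit_within_near_bed_zone(self):
        spec = generate_scenario("spawning", seed=9)
        for v in spec.vortices:
            yc, zc = v.center
            assert zc <= float(spec.bed.z_bed(np.array([yc]))[0]) + 1.3

    def test_same_seed_gives_identical_scenarios(self):
        a = generate_scenario("transition", seed=21)
        b = generate_scenario("transition", seed=21)
        assert a == b

    @pytest.mark.parametrize("label,target", [("spawning", 0.30), ("nonspawning", 0.10)])
    def test_calibration_hits_target_within_tolerance(self, label, target):
        spec = calibrate_circulation(label, target, tol=0.01)
        g = evaluate_velocity(
            spec, build_section_geometry(spec.bed, spec.ny, spec.nz, spec.water_surface)
        )
        mean = mean_vorticity(compute_cell_vorticity(g), g.wet)
        assert abs(mean - target) <= 0.01 * target
        assert spec.achieved_mean == pytest.approx(mean)

    def test_zero_tolerance_is_rejected(self):
        with pytest.raises(ContractError):
            calibrate_circulation("spawning", 0.3, tol=0.0)

    def test_target_below_floor_is_unreachable(self):
        with pytest.raises(CalibrationError):
            calibrate_circulation("nonspawning", 0.05, tol=0.01)
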