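import math

import numpy as np
import pytest

from retisim.eye_iol import (
    ALCON_MATERIAL,
    BAUSCH_MATERIAL,
    PACKAGED_ACD,
    PACKAGED_LENSES,
    assemble_pseudophakic,
    build_aphakic_eye,
    build_arizona_eye,
    chromatic_refraction_difference,
    depth_of_focus,
    make_monofocal_iol,
    make_plateau_edof_iol,
    make_zonal_sa_edof_iol,
    packaged_eye,
    packaged_iol,
    paraxial_focus_vergence,
    radial_power_profile,
    through_focus_curve,
)
from retisim.optics_core import LAMBDA_D, VISIBLE_RANGE, RayBundle, trace_sequential
from retisim.scene import SpectralSamplingPlan


class TestArizonaEye:
    def test_unaccommodated_eye_is_emmetropic(self):
        eye = build_arizona_eye(0.0)
        assert abs(paraxial_focus_vergence(eye, LAMBDA_D)) < 0.25

    def test_same_wavelength_gives_zero_difference(self):
        eye = build_arizona_eye(0.0)
        assert chromatic_refraction_difference(eye, 0.55, 0.55) == 0.0

    def test_chromatic_ordering_blue_more_myopic(self):
        eye = build_arizona_eye(0.0)
        assert paraxial_focus_vergence(eye, 0.45) > paraxial_focus_vergence(eye, 0.65)

    def test_lca_over_visible_range_near_published(self):
        eye = build_arizona_eye(0.0)
        lca = chromatic_refraction_difference(eye, *VISIBLE_RANGE)
        assert lca == pytest.approx(2.5, abs=0.4)

    def test_lca_monotone_in_interval_width(self):
        eye = build_arizona_eye(0.0)
        prev = 0.0
        for lo, hi in [(0.5, 0.6), (0.46, 0.64), (0.42, 0.7), (0.39, 0.75)]:
            cur = chromatic_refraction_difference(eye, lo, hi)
            assert cur >= prev
            prev = cur

    def test_negative_accommodation_rejected(self):
        with pytest.raises(ValueError):
            build_arizona_eye(-1.0)


class TestMonofocal:
    def test_central_power_matches_label(self, mono_eye):
        prof = radial_power_profile(mono_eye, np.array([0.05]))
        assert prof.power[0] == pytest.approx(20.0, abs=0.25)

    def test_profile_spread_small(self, mono_eye):
        prof = radial_power_profile(mono_eye, np.linspace(0.1, 2.25, 10))
        spread = np.nanmax(prof.power) - np.nanmin(prof.power)
        assert spread <= 0.75

    def test_material_round_trip(self):
        iol = packaged_iol("monofocal")
        assert iol.material.n_d == 1.5542
        assert iol.dispersion.n_d == pytest.approx(1.5542, abs=1e-12)

    def test_power_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_monofocal_iol(45.0)

    def test_dual_route_power_check(self, mono_eye):
        """Real-ray pencil power at the axis agrees with the independent
        paraxial solve."""
        prof = radial_power_profile(mono_eye, np.array([0.05]))
        paraxial = mono_eye.iol.nominal_power + \
            paraxial_focus_vergence(mono_eye, LAMBDA_D)
        assert prof.power[0] == pytest.approx(paraxial, abs=0.1)


class TestPlateauEdof:
    def test_peripheral_power_at_base(self, plateau_eye):
        prof = radial_power_profile(plateau_eye, np.array([1.6, 1.9, 2.2]))
        np.testing.assert_allclose(prof.power, 20.0, atol=0.3)

    def test_elevated_zone_power(self, plateau_eye):
        prof = radial_power_profile(plateau_eye, np.array([0.7, 0.825, 0.95, 1.9]))
        assert np.all(prof.power[:3] > prof.power[3] + 0.5)

    def test_segment_slope_example(self):
        # 1 um over 100 um -> atan(0.01) = 0.573 deg, printed as 0.6
        slope_deg = math.degrees(math.atan(0.001 / 0.1))
        assert slope_deg == pytest.approx(0.573, abs=1e-3)
        assert round(slope_deg, 1) == 0.6

    def test_zero_add_reduces_to_monofocal(self):
        flat = make_plateau_edof_iol(20.0, add=0.0, reference_acd=4.10)
        mono = make_monofocal_iol(20.0, reference_acd=4.10)
        r = np.linspace(0.0, 2.9, 200)
        np.testing.assert_allclose(flat.anterior.sag(r), mono.anterior.sag(r),
                                   atol=1e-9)

    def test_zone_order_validated(self):
        with pytest.raises(ValueError):
            make_plateau_edof_iol(20.0, zone_inner=1.1, zone_outer=0.55)


class TestZonalSaEdof:
    def test_outer_zone_power_at_base(self, zonal_eye):
        prof = radial_power_profile(zonal_eye, np.array([1.7, 2.0, 2.3]))
        np.testing.assert_allclose(prof.power, 20.0, atol=0.3)

    def test_zero_coefficients_reduce_to_monofocal(self):
        flat = make_zonal_sa_edof_iol(20.0, sa4=0.0, sa6=0.0, reference_acd=3.91)
        mono = make_monofocal_iol(20.0, material=BAUSCH_MATERIAL,
                                  reference_acd=3.91)
        r = np.linspace(0.0, 2.9, 200)
        np.testing.assert_allclose(flat.anterior.sag(r), mono.anterior.sag(r),
                                   atol=1e-12)

    def test_material_abbe_round_trip(self):
        iol = packaged_iol("zonal-sa-edof")
        assert iol.material.V_d == 43.0
        assert iol.dispersion.V_d == pytest.approx(43.0, abs=1e-9)

    def test_same_sign_coefficients_rejected(self):
        with pytest.raises(ValueError):
            make_zonal_sa_edof_iol(20.0, sa4=1.0, sa6=0.5)


class TestAssembly:
    @pytest.mark.parametrize("lens", PACKAGED_LENSES)
    def test_packaged_acd_builds_valid_stack(self, lens):
        eye = packaged_eye(lens)
        zs = [s.vertex_z for s in eye.stack.surfaces]
        assert zs == sorted(zs)
        assert eye.acd == PACKAGED_ACD[lens]

    def test_acd_beyond_retina_rejected(self):
        iol = packaged_iol("monofocal")
        with pytest.raises(ValueError):
            assemble_pseudophakic(build_aphakic_eye(), iol, 30.0)

    def test_acd_inside_anterior_chamber_rejected(self):
        iol = packaged_iol("monofocal")
        with pytest.raises(ValueError):
            assemble_pseudophakic(build_aphakic_eye(), iol, 1.0)


class TestPowerProfile:
    def test_monotone_grid_required(self, mono_eye):
        with pytest.raises(ValueError):
            radial_power_profile(mono_eye, np.array([1.0, 0.5]))

    def test_empty_grid_rejected(self, mono_eye):
        with pytest.raises(ValueError):
            radial_power_profile(mono_eye, np.array([]))

    def test_vignetted_radius_is_nan(self, mono_eye):
        prof = radial_power_profile(mono_eye, np.array([0.5, 3.4]))
        assert np.isfinite(prof.power[0])
        assert np.isnan(prof.power[1])

    def test_axial_limit_handled(self, mono_eye):
        prof = radial_power_profile(mono_eye, np.array([0.0, 0.05]))
        assert np.all(np.isfinite(prof.power))
        assert prof.power[0] == pytest.approx(prof.power[1], abs=0.05)

    def test_grid_insensitivity(self, mono_eye):
        r = np.array([0.4, 1.2, 2.0])
        a = radial_power_profile(mono_eye, r, pencil_half_width=0.025)
        b = radial_power_profile(mono_eye, r, pencil_half_width=0.015)
        np.testing.assert_allclose(a.power, b.power, atol=0.05)


class TestAxialSymmetry:
    def test_rotated_bundle_traces_to_rotated_output(self, mono_eye):
        n = 64
        h = np.linspace(0.1, 1.2, n)
        b_x = RayBundle.parallel(h, LAMBDA_D, z=-1.0)
        out_x = trace_sequential(b_x, mono_eye.stack)
        # same bundle rotated 90 degrees about the axis
        origin = np.column_stack([np.zeros(n), h, np.full(n, -1.0)])
        b_y = RayBundle(origin, np.tile([0.0, 0.0, 1.0], (n, 1)),
                        np.full(n, LAMBDA_D), np.ones(n), np.ones(n, bool))
        out_y = trace_sequential(b_y, mono_eye.stack)
        np.testing.assert_allclose(out_x.origin[:, 0], out_y.origin[:, 1],
                                   atol=1e-9)
        np.testing.assert_allclose(out_x.origin[:, 1], -out_y.origin[:, 0],
                                   atol=1e-9)


class TestThroughFocus:
    VERG = np.round(np.arange(0.0, 2.01, 0.2), 2)

    def test_monofocal_sharp_at_distance_worsens_to_near(self, mono_eye, d65_plan):
        m = through_focus_curve(mono_eye, self.VERG, spectrum=d65_plan,
                                n_rays=8000, seed=3)
        assert self.VERG[np.argmin(m)] <= 0.4
        assert m[self.VERG.tolist().index(1.6)] > 2.0 * m.min()
        # strictly worsening from 0.6 up
        tail = m[3:]
        assert np.all(np.diff(tail) > 0)

    def test_plateau_flatter_than_monofocal(self, mono_eye, plateau_eye, d65_plan):
        sel = self.VERG <= 1.5
        m_mono = through_focus_curve(mono_eye, self.VERG[sel], spectrum=d65_plan,
                                     n_rays=8000, seed=3)
        m_plat = through_focus_curve(plateau_eye, self.VERG[sel], spectrum=d65_plan,
                                     n_rays=8000, seed=3)
        assert m_plat.max() / m_plat.min() < m_mono.max() / m_mono.min()

    def test_duplicate_vergences_identical(self, mono_eye):
        m = through_focus_curve(mono_eye, [0.5, 1.0, 0.5], n_rays=4000, seed=9)
        assert m[0] == m[2]

    def test_seeded_bit_reproducibility(self, mono_eye, d65_plan):
        a = through_focus_curve(mono_eye, [0.0, 1.0], spectrum=d65_plan,
                                n_rays=4000, seed=11)
        b = through_focus_curve(mono_eye, [0.0, 1.0], spectrum=d65_plan,
                                n_rays=4000, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_empty_vergences_rejected(self, mono_eye):
        with pytest.raises(ValueError):
            through_focus_curve(mono_eye, [])


class TestDepthOfFocus:
    def test_flat_curve_spans_full_range(self):
        v = np.linspace(0.0, 2.0, 21)
        assert depth_of_focus(v, np.ones(21)) == pytest.approx(2.0, abs=0.011)

    def test_vee_curve_width(self):
        v = np.linspace(-1.0, 1.0, 201)
        metric = 1.0 + np.abs(v)
        # threshold 2*1 = 2 -> |v| <= 1 -> width 2
        assert depth_of_focus(v, metric, criterion=2.0) == pytest.approx(2.0, abs=0.02)
        assert depth_of_focus(v, metric, criterion=1.5) == pytest.approx(1.0, abs=0.02)

    def test_monofocal_smaller_than_both_edof(self, mono_eye, plateau_eye,
                                              zonal_eye, d65_plan):
        verg = np.round(np.arange(0.0, 2.01, 0.1), 2)
        spans = {}
        for name, eye in [("mono", mono_eye), ("plateau", plateau_eye),
                          ("zonal", zonal_eye)]:
            m = through_focus_curve(eye, verg, spectrum=d65_plan,
                                    n_rays=20000, seed=5)
            spans[name] = depth_of_focus(verg, m)
        assert spans["mono"] < spans["plateau"]
        assert spans["mono"] < spans["zonal"]

    def test_lca_sign_for_packaged_eyes(self):
        for lens in PACKAGED_LENSES:
            eye = packaged_eye(lens)
            assert chromatic_refraction_difference(eye, 0.45, 0.65) > 0
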