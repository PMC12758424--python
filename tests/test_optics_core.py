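import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retisim.optics_core import (
    AIR,
    LAMBDA_C,
    LAMBDA_D,
    LAMBDA_F,
    ConicSurface,
    DispersionModel,
    MaterialSpec,
    OpticalStack,
    PlaneSurface,
    RampPlateauDeformation,
    RayBundle,
    StopSurface,
    WindowedPolyDeformation,
    ZonalSurface,
    evaluate_index,
    fit_dispersion,
    hurb_bend,
    hurb_sigma,
    intersect,
    refract,
    trace_sequential,
)

ALCON = MaterialSpec(1.5542, 37.0)
BAUSCH = MaterialSpec(1.540, 43.0)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

class TestFitDispersion:
    def test_center_index_reproduced_exactly(self):
        model = fit_dispersion(ALCON, 0.014)
        assert model.n(LAMBDA_D) == pytest.approx(1.5542, abs=1e-12)

    def test_fdc_spread_matches_abbe_definition(self):
        # (n_F - n_C) = (n_d - 1)/V = 0.540/43 = 0.0125581...
        model = fit_dispersion(BAUSCH)
        spread = model.n(LAMBDA_F) - model.n(LAMBDA_C)
        assert spread == pytest.approx(0.540 / 43.0, abs=1e-12)

    def test_dispersionless_limit(self):
        model = fit_dispersion(MaterialSpec(1.5, math.inf))
        assert model.B == 0.0
        for wl in (0.4, 0.55, 0.7):
            assert model.n(wl) == 1.5

    def test_normal_dispersion_has_positive_B(self):
        assert fit_dispersion(ALCON).B > 0

    @pytest.mark.parametrize("nd,vd", [(0.99, 37.0), (1.0, 37.0), (1.5, 0.0),
                                       (1.5, -3.0)])
    def test_nonphysical_inputs_rejected(self, nd, vd):
        with pytest.raises(ValueError):
            fit_dispersion(MaterialSpec(nd, vd))

    @given(nd=st.floats(1.3, 1.9), vd=st.floats(15.0, 90.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, nd, vd):
        model = fit_dispersion(MaterialSpec(nd, vd))
        assert model.n_d == pytest.approx(nd, abs=1e-10)
        assert model.V_d == pytest.approx(vd, abs=max(1e-10 * vd, 1e-8))


class TestEvaluateIndex:
    def test_alcon_at_d_line(self):
        assert evaluate_index(fit_dispersion(ALCON), LAMBDA_D) == \
            pytest.approx(1.5542, abs=1e-12)

    def test_constant_when_B_zero(self):
        m = DispersionModel(A=1.4, B=0.0)
        assert np.allclose(m.n(np.linspace(0.4, 0.7, 5)), 1.4)

    def test_blue_index_exceeds_red(self):
        m = fit_dispersion(ALCON)
        assert m.n(LAMBDA_F) > m.n(LAMBDA_C)

    def test_strictly_decreasing_over_visible(self):
        m = fit_dispersion(ALCON)
        n = m.n(np.linspace(0.38, 0.78, 100))
        assert np.all(np.diff(n) < 0)

    def test_pole_rejected(self):
        m = fit_dispersion(ALCON, 0.014)
        with pytest.raises(ValueError):
            m.n(math.sqrt(0.014))


# ---------------------------------------------------------------------------
# refraction
# ---------------------------------------------------------------------------

class TestRefract:
    def test_normal_incidence_unchanged(self):
        d = np.array([0.0, 0.0, 1.0])
        out, tir = refract(d, np.array([0.0, 0.0, 1.0]), 1.0, 1.7)
        assert not tir
        np.testing.assert_allclose(out, d, atol=1e-15)

    def test_equal_indices_unchanged(self):
        d = np.array([0.3, 0.1, 0.9486832980505138])
        d /= np.linalg.norm(d)
        out, tir = refract(d, np.array([0.0, 0.0, 1.0]), 1.5, 1.5)
        np.testing.assert_allclose(out, d, atol=1e-12)

    def test_45_degree_example(self):
        # asin(sin 45 / 1.5) = 28.1255 degrees
        d = np.array([math.sin(math.radians(45)), 0.0, math.cos(math.radians(45))])
        out, tir = refract(d, np.array([0.0, 0.0, 1.0]), 1.0, 1.5)
        angle = math.degrees(math.asin(out[0]))
        assert angle == pytest.approx(28.1255, abs=1e-3)

    def test_total_internal_reflection_flagged(self):
        d = np.array([math.sin(math.radians(60)), 0.0, math.cos(math.radians(60))])
        _, tir = refract(d, np.array([0.0, 0.0, 1.0]), 1.5, 1.0)
        assert tir

    def test_snell_oracle_many_random_interfaces(self, rng):
        n = 10_000
        theta = rng.uniform(0.0, math.pi / 2 - 0.05, n)
        phi = rng.uniform(0, 2 * math.pi, n)
        d = np.column_stack([np.sin(theta) * np.cos(phi),
                             np.sin(theta) * np.sin(phi), np.cos(theta)])
        nrm = np.tile([0.0, 0.0, 1.0], (n, 1))
        n1 = rng.uniform(1.0, 1.8, n)
        n2 = rng.uniform(1.0, 1.8, n)
        out, tir = refract(d, nrm, n1, n2)
        sin1 = np.linalg.norm(d[:, :2], axis=1)
        sin2 = np.linalg.norm(out[:, :2], axis=1)
        ok = ~tir
        np.testing.assert_allclose(n1[ok] * sin1[ok], n2[ok] * sin2[ok],
                                   atol=1e-12)

    def test_reversibility(self, rng):
        n = 500
        theta = rng.uniform(0.0, 0.9, n)
        d = np.column_stack([np.sin(theta), np.zeros(n), np.cos(theta)])
        nrm = np.tile([0.0, 0.0, 1.0], (n, 1))
        out, tir = refract(d, nrm, 1.0, 1.6)
        back, _ = refract(-out[~tir], nrm[~tir], 1.6, 1.0)
        np.testing.assert_allclose(back, -d[~tir], atol=1e-9)


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------

class TestIntersect:
    def test_on_axis_hits_vertex(self):
        surf = ConicSurface(5.0, 3.0, R=10.0, k=0.0)
        b = RayBundle.parallel([0.0], 0.55, z=0.0)
        pts, normals, hit = intersect(b, surf)
        assert hit[0]
        np.testing.assert_allclose(pts[0], [0.0, 0.0, 5.0], atol=1e-12)
        np.testing.assert_allclose(normals[0], [0.0, 0.0, 1.0], atol=1e-12)

    def test_sphere_sag_closed_form(self):
        # z = 10 - sqrt(100 - 9) = 0.460608 mm at height 3
        surf = ConicSurface(0.0, 5.0, R=10.0, k=0.0)
        b = RayBundle.parallel([3.0], 0.55, z=-1.0)
        pts, _, hit = intersect(b, surf)
        assert hit[0]
        assert pts[0, 2] == pytest.approx(10.0 - math.sqrt(91.0), abs=1e-9)

    def test_plane_path_length(self):
        surf = PlaneSurface(4.0, 10.0)
        d = np.array([[0.6, 0.0, 0.8]])
        b = RayBundle(np.array([[0.0, 0.0, 0.0]]), d, [0.55], [1.0], [True])
        pts, _, hit = intersect(b, surf)
        assert hit[0]
        assert pts[0, 0] == pytest.approx(3.0, abs=1e-12)

    def test_ray_beyond_semi_diameter_vignetted(self):
        surf = ConicSurface(0.0, 2.0, R=10.0, k=0.0)
        b = RayBundle.parallel([2.5], 0.55, z=-1.0)
        _, _, hit = intersect(b, surf)
        assert not hit[0]

    def test_backward_surface_misses(self):
        surf = PlaneSurface(-5.0, 10.0)
        b = RayBundle.parallel([0.0], 0.55, z=0.0)
        _, _, hit = intersect(b, surf)
        assert not hit[0]

    def test_newton_solution_on_zonal_sag(self):
        deform = RampPlateauDeformation(dc=0.01, r1=0.5, r2=1.0, r3=1.3)
        surf = ZonalSurface(2.0, 3.0, R=15.0, k=-3.0, deformation=deform)
        heights = np.linspace(0.1, 2.5, 17)
        b = RayBundle.parallel(heights, 0.55, z=0.0)
        pts, _, hit = intersect(b, surf)
        assert np.all(hit)
        r = np.hypot(pts[:, 0], pts[:, 1])
        residual = pts[:, 2] - 2.0 - surf.sag(r)
        assert np.max(np.abs(residual)) < 1e-9


# ---------------------------------------------------------------------------
# sequential tracing
# ---------------------------------------------------------------------------

def _single_sphere_stack(n_after=1.5542, R=10.0):
    glass = DispersionModel(A=n_after, B=0.0)
    return OpticalStack([ConicSurface(0.0, 5.0, R=R, k=0.0)], [glass], AIR)


class TestTraceSequential:
    def test_paraxial_back_focal_distance(self):
        # n' R / (n' - 1) = 1.5542 * 10 / 0.5542 = 28.043 mm
        stack = _single_sphere_stack()
        b = RayBundle.parallel([0.05, 0.1], LAMBDA_D, z=-1.0)
        out = trace_sequential(b, stack)
        # propagate each refracted ray to its axis crossing
        t = -out.origin[:, 0] / out.direction[:, 0]
        z_cross = out.origin[:, 2] + t * out.direction[:, 2]
        expected = 1.5542 * 10.0 / 0.5542
        np.testing.assert_allclose(z_cross, expected, rtol=1e-3)

    def test_empty_stack_is_identity(self):
        stack = OpticalStack([], [], AIR)
        b = RayBundle.parallel([0.3, 0.7], 0.5, z=-2.0)
        out = trace_sequential(b, stack)
        np.testing.assert_array_equal(out.origin, b.origin)
        np.testing.assert_array_equal(out.direction, b.direction)

    def test_weight_conservation(self, rng):
        stack = _single_sphere_stack()
        heights = rng.uniform(-4.0, 4.0, 300)
        b = RayBundle.parallel(heights, 0.55, z=-1.0)
        out = trace_sequential(b, stack)
        surviving = out.weight[out.alive].sum()
        assert surviving <= b.weight.sum() + 1e-12
        # no vignetting for |h| < semi-diameter on this geometry
        assert np.all(out.alive == (np.abs(heights) <= 5.0))
        np.testing.assert_allclose(out.weight, b.weight)

    def test_vignetted_count_matches_brute_force(self, rng):
        stop = StopSurface(1.0, 6.0, stop_diameter=2.0)
        stack = OpticalStack([stop, PlaneSurface(5.0, 6.0)], [AIR, AIR], AIR)
        heights = rng.uniform(-3.0, 3.0, 500)
        b = RayBundle.parallel(heights, 0.55, z=0.0)
        out = trace_sequential(b, stack, rng=None)
        assert out.alive.sum() == int(np.sum(np.abs(heights) <= 1.0))

    def test_misordered_stack_rejected(self):
        s1 = ConicSurface(2.0, 3.0, R=10.0)
        s2 = ConicSurface(1.0, 3.0, R=10.0)
        with pytest.raises(ValueError):
            OpticalStack([s1, s2], [AIR, AIR], AIR)


# ---------------------------------------------------------------------------
# HURB
# ---------------------------------------------------------------------------

class TestHurb:
    def test_sigma_value_example(self):
        # lambda/(2 pi d) with lambda=0.55 um, d=0.5 mm
        sig_r, _ = hurb_sigma(1.0, 0.55, 1.5)
        assert sig_r == pytest.approx(1.7507e-4, rel=1e-3)

    def test_sigma_shrinks_with_distance(self):
        s_near, _ = hurb_sigma(1.4, 0.55, 1.5)
        s_far, _ = hurb_sigma(0.0, 0.55, 1.5)
        assert s_far < s_near
        big, _ = hurb_sigma(0.0, 0.55, 500.0)
        assert big < 1e-6

    def test_ensemble_mean_zero(self):
        n = 200_000
        stop = StopSurface(0.0, 3.0, stop_diameter=3.0)
        origin = np.tile([1.0, 0.0, 0.0], (n, 1))
        direction = np.tile([0.0, 0.0, 1.0], (n, 1))
        b = RayBundle(origin, direction, np.full(n, 0.55), np.ones(n),
                      np.ones(n, bool))
        out = hurb_bend(b, stop, np.random.default_rng(7))
        dx = out.direction[:, 0]
        sig_r, _ = hurb_sigma(1.0, 0.55, 1.5)
        se = sig_r / math.sqrt(n)
        assert abs(dx.mean()) < 3 * se

    def test_sample_std_matches_rule(self):
        n = 200_000
        stop = StopSurface(0.0, 3.0, stop_diameter=3.0)
        origin = np.tile([1.0, 0.0, 0.0], (n, 1))
        direction = np.tile([0.0, 0.0, 1.0], (n, 1))
        b = RayBundle(origin, direction, np.full(n, 0.55), np.ones(n),
                      np.ones(n, bool))
        out = hurb_bend(b, stop, np.random.default_rng(8))
        sig_r, sig_t = hurb_sigma(1.0, 0.55, 1.5)
        assert np.std(out.direction[:, 0]) == pytest.approx(sig_r, rel=0.02)
        assert np.std(out.direction[:, 1]) == pytest.approx(sig_t, rel=0.02)

    def test_outside_aperture_vignetted_not_bent(self):
        stop = StopSurface(0.0, 3.0, stop_diameter=2.0)
        b = RayBundle(np.array([[1.5, 0.0, 0.0]]), np.array([[0.0, 0.0, 1.0]]),
                      [0.55], [1.0], [True])
        out = hurb_bend(b, stop, np.random.default_rng(0))
        assert not out.alive[0]
        np.testing.assert_array_equal(out.direction, [[0.0, 0.0, 1.0]])

    def test_seeded_determinism_bit_identical(self):
        stop = StopSurface(0.0, 3.0, stop_diameter=3.0)

        def run():
            n = 1000
            origin = np.column_stack([np.linspace(-1.2, 1.2, n), np.zeros(n),
                                      np.zeros(n)])
            b = RayBundle(origin, np.tile([0.0, 0.0, 1.0], (n, 1)),
                          np.full(n, 0.55), np.ones(n), np.ones(n, bool))
            return hurb_bend(b, stop, np.random.default_rng(42)).direction

        np.testing.assert_array_equal(run(), run())


# ---------------------------------------------------------------------------
# deformations and serialization
# ---------------------------------------------------------------------------

class TestDeformations:
    def test_plateau_is_pure_offset_beyond_ramp(self):
        d = RampPlateauDeformation(dc=0.01, r1=0.55, r2=1.1, r3=1.35)
        r = np.linspace(1.35, 3.0, 20)
        assert np.allclose(d.slope(r), 0.0)
        assert np.allclose(d.value(r), d.value(np.array(1.35)))

    def test_plateau_zero_inside_inner_zone(self):
        d = RampPlateauDeformation(dc=0.01, r1=0.55, r2=1.1, r3=1.35)
        r = np.linspace(0.0, 0.54, 10)
        assert np.allclose(d.value(r), 0.0)

    def test_plateau_continuity(self):
        d = RampPlateauDeformation(dc=0.02, r1=0.5, r2=1.0, r3=1.3)
        for edge in (0.5, 1.0, 1.3):
            lo = d.value(np.array(edge - 1e-9))
            hi = d.value(np.array(edge + 1e-9))
            assert abs(hi - lo) < 1e-10

    def test_windowed_poly_outer_zone_is_offset(self):
        d = WindowedPolyDeformation(a4=1e-4, a6=-4e-5, r_inner=1.0, r_outer=1.3)
        r = np.linspace(1.3, 3.0, 15)
        assert np.allclose(d.slope(r), 0.0)
        assert np.allclose(d.value(r), d.value(np.array(2.0)))

    def test_stack_serialization_round_trip(self):
        deform = WindowedPolyDeformation(a4=1e-4, a6=-4e-5, r_inner=1.0,
                                         r_outer=1.3)
        surfaces = [
            ConicSurface(0.0, 6.0, R=7.8, k=-0.25),
            StopSurface(3.5, 6.0, stop_diameter=3.0),
            ZonalSurface(4.1, 3.0, R=21.0, k=-5.0, poly_coeffs=(1e-5,),
                         deformation=deform),
            PlaneSurface(24.0, 6.0),
        ]
        media = [fit_dispersion(ALCON)] * 4
        stack = OpticalStack(surfaces, media, AIR)
        clone = OpticalStack.from_dict(stack.to_dict())
        r = np.linspace(0.0, 2.5, 30)
        for s0, s1 in zip(stack.surfaces, clone.surfaces):
            assert type(s0) is type(s1)
            np.testing.assert_allclose(s0.sag(r), s1.sag(r), atol=1e-15)
        import json
        json.dumps(stack.to_dict())  # JSON-serialisable
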