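"""Geometric transport fractions: lenses, overlaps, fibers, no optics."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from photonbudget import (
    FiberSpec,
    InvalidParameterError,
    LensSpec,
    NoRealImageError,
    SourceSpec,
    cone_to_solid_angle,
    conjugate_distance,
    fiber_capture_fraction,
    fiber_half_angle,
    fiber_solid_angle,
    image_spot,
    no_optics_fraction,
    overlap_fractions,
    sample_to_lens_fraction,
    source_to_fiber_rate,
    source_to_lens_fraction,
)
from photonbudget.coupling import circle_strip_overlap_area

from conftest import quadrature_circle_strip_area

LENS = LensSpec(radius=0.75, focal_length=1.5)


class TestSourceToLens:
    def test_narrow_cone_fully_intercepted(self):
        omega = cone_to_solid_angle(10.0)
        assert source_to_lens_fraction(omega, LENS, 2.0) == 1.0

    def test_wide_cone_partially_intercepted(self):
        omega = cone_to_solid_angle(60.0)
        expected = math.pi * 0.75**2 / (omega * 100.0)
        assert source_to_lens_fraction(omega, LENS, 10.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.020993, rel=1e-4)

    def test_zero_distance_rejected(self):
        with pytest.raises(InvalidParameterError):
            source_to_lens_fraction(1.0, LENS, 0.0)

    def test_exact_cap_form_close_to_flat_disk_at_small_angles(self):
        omega = cone_to_solid_angle(60.0)
        flat = source_to_lens_fraction(omega, LENS, 10.0)
        exact = source_to_lens_fraction(omega, LENS, 10.0, exact=True)
        assert exact == pytest.approx(flat, rel=0.01)
        assert exact < flat  # flat disk overestimates the subtended cap


class TestConjugateAndSpot:
    def test_symmetric_conjugates_at_twice_focal(self):
        assert conjugate_distance(1.5, 3.0) == pytest.approx(3.0, rel=1e-12)

    def test_general_conjugate(self):
        assert conjugate_distance(1.5, 4.5) == pytest.approx(2.25, rel=1e-12)

    def test_object_at_focus_has_no_real_image(self):
        with pytest.raises(NoRealImageError):
            conjugate_distance(1.5, 1.5)

    @given(focal=st.floats(0.1, 10.0), factor=st.floats(1.01, 50.0))
    def test_thin_lens_relation_holds_exactly(self, focal, factor):
        x1 = focal * factor
        x2 = conjugate_distance(focal, x1)
        assert 1.0 / focal - 1.0 / x1 - 1.0 / x2 == pytest.approx(0.0, abs=1e-10)

    def test_unit_magnification_preserves_area(self):
        assert image_spot(0.04, 3.0, 3.0, "squared") == pytest.approx(0.04)
        assert image_spot(0.04, 3.0, 3.0, "linear") == pytest.approx(0.04)

    def test_demagnification_modes(self):
        # x2/x1 = 1/2: area scales by 1/4 (physical) or 1/2 (literal)
        assert image_spot(0.04, 4.5, 2.25, "squared") == pytest.approx(0.01)
        assert image_spot(0.04, 4.5, 2.25, "linear") == pytest.approx(0.02)


class TestOverlapFractions:
    def test_spot_inside_channel_fully_used(self):
        ov = overlap_fractions(0.004, None, 0.01, "microchannel")
        assert ov.f_into_channel == 1.0

    def test_tangent_spot_fully_used(self):
        ov = overlap_fractions(0.005, None, 0.01, "microchannel")
        assert ov.f_into_channel == pytest.approx(1.0)

    @pytest.mark.parametrize("spot_r, half_w", [(5.0, 1.0), (0.02, 0.005), (1.0, 0.9)])
    def test_circle_strip_matches_quadrature(self, spot_r, half_w):
        analytic = circle_strip_overlap_area(spot_r, half_w)
        numeric = quadrature_circle_strip_area(spot_r, half_w)
        assert analytic == pytest.approx(numeric, abs=1e-6)

    def test_wide_spot_fraction_value(self):
        # r = 5 * half-width: fraction from the quadrature oracle
        ov = overlap_fractions(5.0, None, 2.0, "microchannel")
        oracle = quadrature_circle_strip_area(5.0, 1.0) / (math.pi * 25.0)
        assert ov.f_into_channel == pytest.approx(oracle, abs=1e-6)

    def test_thin_film_has_no_lateral_clipping(self):
        ov = overlap_fractions(0.5, None, 0.01, "thin_film")
        assert ov.f_into_channel == 1.0 and ov.f_viewed == 1.0

    def test_thin_film_view_is_concentric_circle_ratio(self):
        ov = overlap_fractions(0.5, 0.25, 0.01, "thin_film")
        assert ov.f_viewed == pytest.approx(0.25)

    def test_channel_triple_intersection_against_quadrature(self):
        spot_r, view_r, half_w = 0.03, 0.02, 0.005
        ov = overlap_fractions(spot_r, view_r, 2 * half_w, "microchannel")
        illuminated = quadrature_circle_strip_area(spot_r, half_w)
        seen = quadrature_circle_strip_area(view_r, half_w)
        assert ov.f_viewed == pytest.approx(seen / illuminated, abs=1e-6)

    def test_view_larger_than_spot_sees_everything(self):
        ov = overlap_fractions(0.02, 0.05, 0.01, "microchannel")
        assert ov.f_viewed == 1.0

    @given(
        spot_r=st.floats(1e-4, 10.0),
        view_r=st.floats(1e-4, 10.0),
        width=st.floats(1e-4, 10.0),
    )
    def test_fractions_always_in_unit_interval(self, spot_r, view_r, width):
        for kind in ("microchannel", "thin_film"):
            ov = overlap_fractions(spot_r, view_r, width, kind)
            assert 0.0 <= ov.f_into_channel <= 1.0
            assert 0.0 <= ov.f_viewed <= 1.0


class TestSampleToLens:
    def test_quarter_ratio(self):
        assert sample_to_lens_fraction(LENS, 1.5) == pytest.approx(0.0625)

    def test_vanishes_at_large_distance(self):
        assert sample_to_lens_fraction(LENS, 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_hemisphere_cap_close_up(self):
        big = LensSpec(radius=10.0, focal_length=1.5)
        assert sample_to_lens_fraction(big, 1.0) == 0.5

    @given(radius=st.floats(1e-3, 100.0), x3=st.floats(1e-3, 100.0))
    def test_never_exceeds_hemisphere(self, radius, x3):
        lens = LensSpec(radius=radius, focal_length=1.0)
        assert 0.0 < sample_to_lens_fraction(lens, x3) <= 0.5


class TestFiber:
    def test_half_angle_air_na_one(self):
        fiber = FiberSpec(core_radius=0.005, numerical_aperture=1.0)
        assert fiber_half_angle(fiber) == pytest.approx(90.0)

    def test_half_angle_typical_na(self):
        fiber = FiberSpec(core_radius=0.005, numerical_aperture=0.22)
        assert fiber_half_angle(fiber) == pytest.approx(12.7090, rel=1e-4)

    def test_half_angle_in_water(self):
        fiber = FiberSpec(
            core_radius=0.005, numerical_aperture=0.22, medium_refractive_index=1.33
        )
        assert fiber_half_angle(fiber) == pytest.approx(
            math.degrees(math.asin(0.22 / 1.33)), rel=1e-9
        )

    def test_na_above_medium_index_rejected(self):
        with pytest.raises(ValueError, match="sin"):
            FiberSpec(
                core_radius=0.005,
                numerical_aperture=1.2,
                medium_refractive_index=1.0,
            )

    def test_solid_angle_from_half_angle(self):
        fiber = FiberSpec(core_radius=0.005, numerical_aperture=0.22)
        expected = 2 * math.pi * (1 - math.cos(math.asin(0.22)))
        assert fiber_solid_angle(fiber) == pytest.approx(expected)


SRC_60 = SourceSpec(
    power=1.0, wavelength=470.0, full_emission_angle=60.0, emitting_area=1e-3
)
FIBER = FiberSpec(core_radius=0.005, numerical_aperture=0.22)


class TestSourceToFiber:
    def test_overfilled_acceptance_area_factor_is_one(self):
        # Omega_F * d^2 >= A_S: rate reduces to pi R_F^2 / (Omega_S d^2)
        d = 0.2
        assert fiber_solid_angle(FIBER) * d**2 > SRC_60.emitting_area
        rate = source_to_fiber_rate(1.0, SRC_60, FIBER, d)
        expected = math.pi * FIBER.core_radius**2 / (SRC_60.solid_angle * d**2)
        assert rate == pytest.approx(expected)

    def test_vanishing_core_collects_nothing(self):
        tiny = FiberSpec(core_radius=1e-9, numerical_aperture=0.22)
        assert source_to_fiber_rate(1.0, SRC_60, tiny, 0.1) < 1e-10

    def test_distance_invariant_while_source_underfilled(self):
        # Omega_F d^2 < A_S: the d^2 factors cancel exactly
        big_src = SourceSpec(
            power=1.0, wavelength=470.0, full_emission_angle=60.0, emitting_area=1.0
        )
        d1, d2 = 0.05, 0.1
        assert fiber_solid_angle(FIBER) * d2**2 < big_src.emitting_area
        r1 = source_to_fiber_rate(1.0, big_src, FIBER, d1)
        r2 = source_to_fiber_rate(1.0, big_src, FIBER, d2)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_never_exceeds_source_rate(self):
        # pathological close-up geometry still capped at P_S
        fat = FiberSpec(core_radius=5.0, numerical_aperture=0.9)
        assert source_to_fiber_rate(1.0, SRC_60, fat, 0.01) <= 1.0

    def test_capture_fraction_saturates_at_acceptance_cone(self):
        close = fiber_capture_fraction(FIBER, 1e-6)
        assert close == pytest.approx(fiber_solid_angle(FIBER) / (4 * math.pi))

    def test_capture_fraction_far_field_is_core_solid_angle(self):
        d = 1.0
        expected = math.pi * FIBER.core_radius**2 / (4 * math.pi * d**2)
        assert fiber_capture_fraction(FIBER, d) == pytest.approx(expected)


class TestNoOptics:
    def test_zero_area_collects_nothing(self):
        assert no_optics_fraction(0.0, 0.5, "isotropic") == 0.0

    def test_isotropic_example(self):
        assert no_optics_fraction(1.0, 0.5, "isotropic") == pytest.approx(
            1.0 / (4 * math.pi * 0.25)
        )

    def test_cone_exactly_covered_aperture_caps_at_one(self):
        omega = cone_to_solid_angle(20.0)
        area = omega * 0.5**2  # aperture matching the footprint
        assert no_optics_fraction(area, 0.5, "cone", omega) == 1.0
        assert no_optics_fraction(2 * area, 0.5, "cone", omega) == 1.0

    def test_isotropic_capped_at_half(self):
        assert no_optics_fraction(100.0, 0.1, "isotropic") == 0.5
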