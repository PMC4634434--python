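"""Fresnel simulator: closed-form limits, oracle cross-checks, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sprfit as sp
from sprfit.optics_sim import GOLD_INDEX_770NM, CHROMIUM_INDEX_770NM

from conftest import parratt_reflectance, stack_to_lists


def bare_interface(n1=1.5125, n2=1.0):
    return sp.OpticalStack(prism_index=n1, layers=(), bulk_index=n2, wavelength_nm=770.0)


class TestFresnelReflectance:
    def test_normal_incidence_closed_form(self):
        # ((n1-n2)/(n1+n2))^2 = 0.04 for 1.5/1.0; angle ~0 within the open domain
        stack = bare_interface(1.5, 1.0)
        for pol in ("TM", "TE"):
            assert sp.fresnel_reflectance(stack, 1e-7, pol) == pytest.approx(0.04, abs=1e-9)

    def test_total_internal_reflection_lossless(self):
        stack = bare_interface(1.5125, 1.0)
        for pol in ("TM", "TE"):
            assert sp.fresnel_reflectance(stack, 50.0, pol) == pytest.approx(1.0, abs=1e-12)

    def test_gold_stack_has_plasmon_dip(self, water_stack):
        """TM dip below 0.15 between 62 and 70 deg, confirmed by the Parratt oracle."""
        angles = np.linspace(62.0, 70.0, 8001)
        r_tm = sp.fresnel_reflectance(water_stack, angles, "TM")
        assert r_tm.min() < 0.15
        n_list, d_list = stack_to_lists(water_stack)
        oracle = np.array(
            [parratt_reflectance(n_list, d_list, 770.0, a, "TM") for a in angles[::200]]
        )
        np.testing.assert_allclose(r_tm[::200], oracle, atol=1e-10)

    def test_agrees_with_parratt_recursion_full_stack(self, water_stack, air_stack):
        for stack in (water_stack, air_stack):
            n_list, d_list = stack_to_lists(stack)
            for angle in (25.0, 41.4, 55.0, 61.8, 67.4, 75.0, 89.0):
                for pol in ("TM", "TE"):
                    got = sp.fresnel_reflectance(stack, angle, pol)
                    want = parratt_reflectance(n_list, d_list, 770.0, angle, pol)
                    assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("angle", [0.0, -5.0, 90.0, 95.0])
    def test_angle_domain_enforced(self, angle):
        with pytest.raises(ValueError):
            sp.fresnel_reflectance(bare_interface(), angle, "TM")

    def test_bad_polarization_rejected(self):
        with pytest.raises(ValueError):
            sp.fresnel_reflectance(bare_interface(), 45.0, "circular")

    @settings(max_examples=200, deadline=None)
    @given(
        n1=st.floats(1.2, 2.0),
        ratio=st.floats(0.3, 0.95),
        angle=st.floats(1.0, 89.0),
        pol=st.sampled_from(["TM", "TE"]),
    )
    def test_bare_interface_matches_two_media_closed_form(self, n1, ratio, angle, pol):
        """Transfer matrix degenerates to the textbook two-media formulas."""
        n2 = n1 * ratio
        stack = bare_interface(n1, n2)
        th = math.radians(angle)
        cos_t = np.emath.sqrt(1 - (n1 * math.sin(th) / n2) ** 2)
        if pol == "TE":
            r = (n1 * math.cos(th) - n2 * cos_t) / (n1 * math.cos(th) + n2 * cos_t)
        else:
            r = (n2 * math.cos(th) - n1 * cos_t) / (n2 * math.cos(th) + n1 * cos_t)
        assert sp.fresnel_reflectance(stack, angle, pol) == pytest.approx(
            float(abs(r) ** 2), abs=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(angle=st.floats(1.0, 89.0), pol=st.sampled_from(["TM", "TE"]))
    def test_energy_bound_absorbing_stack(self, water_stack, angle, pol):
        r = sp.fresnel_reflectance(water_stack, angle, pol)
        assert 0.0 <= r <= 1.0

    def test_lossless_multilayer_above_critical_reflects_fully(self):
        stack = sp.OpticalStack(
            prism_index=1.5125,
            layers=((1.38 + 0j, 120.0), (1.7 + 0j, 80.0)),
            bulk_index=1.0,
            wavelength_nm=770.0,
        )
        for angle in np.linspace(42.0, 89.0, 25):
            for pol in ("TM", "TE"):
                assert sp.fresnel_reflectance(stack, angle, pol) == pytest.approx(
                    1.0, abs=1e-12
                )


class TestSimulateCurve:
    def test_lossless_all_above_critical_ratio_is_one(self):
        stack = bare_interface(1.5, 1.0)  # critical at 41.81
        geom = sp.DetectorGeometry(n_pixels=64, span_deg=7.296, start_deg=45.0)
        curve = sp.simulate_spr_curve(stack, geom)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-12)

    def test_water_minimum_right_of_critical_rise(self, water_stack):
        geom = sp.default_geometry(start_deg=60.0)  # 60.0 - 67.296
        curve = sp.simulate_spr_curve(water_stack, geom)
        i_min = int(np.argmin(curve.values))
        assert (curve.values == curve.values[i_min]).sum() == 1
        knee = sp.theoretical_critical_angle(1.333, 1.5125)
        assert curve.angles_deg[i_min] > knee

    def test_air_minimum_location(self, air_curve):
        a_min = air_curve.angles_deg[np.argmin(air_curve.values)]
        assert 41.3 < a_min < 44.0

    def test_continuity_between_pixels(self, water_curve, air_curve):
        for curve in (water_curve, air_curve):
            assert np.max(np.abs(np.diff(curve.values))) < 0.15

    def test_window_outside_physical_range_rejected(self, water_stack):
        geom = sp.DetectorGeometry(n_pixels=64, span_deg=10.0, start_deg=85.0)
        with pytest.raises(ValueError):
            sp.simulate_spr_curve(water_stack, geom)


class TestTheoreticalCriticalAngle:
    @pytest.mark.parametrize(
        "n_bulk,n_prism,expected",
        [
            (1.0, 2.0, 30.0),
            (1.0, 1.5125, math.degrees(math.asin(1.0 / 1.5125))),
            (1.330, 1.5125, math.degrees(math.asin(1.330 / 1.5125))),
        ],
    )
    def test_arcsine_values(self, n_bulk, n_prism, expected):
        assert sp.theoretical_critical_angle(n_bulk, n_prism) == pytest.approx(
            expected, abs=1e-12
        )

    def test_air_bk7_value(self):
        assert sp.theoretical_critical_angle(1.0, 1.5125) == pytest.approx(41.3882, abs=1e-4)

    def test_no_critical_angle_when_bulk_exceeds_prism(self):
        with pytest.raises(ValueError):
            sp.theoretical_critical_angle(1.6, 1.5125)


class TestSynthesizeImages:
    def test_zero_noise_round_trip_exact(self, water_stack, water_geometry, water_curve):
        raw = sp.synthesize_image_set(water_stack, water_geometry, n_rows=8)
        ratio = sp.normalize_images(raw)
        curve = sp.extract_curve(ratio, row_band=(0, 7), geometry=water_geometry)
        np.testing.assert_allclose(curve.values, water_curve.values, atol=1e-12)

    def test_same_seed_bit_identical(self, water_stack, water_geometry):
        noise = sp.NoiseSpec(dark_sd=1.0, shot_sd=0.01, seed=1234)
        a = sp.synthesize_image_set(water_stack, water_geometry, n_rows=4, noise=noise)
        b = sp.synthesize_image_set(water_stack, water_geometry, n_rows=4, noise=noise)
        for x, y in ((a.dark, b.dark), (a.te, b.te), (a.tm, b.tm)):
            np.testing.assert_array_equal(x, y)

    def test_noisy_curve_within_three_sigma(self, water_stack, water_curve):
        geom = sp.default_geometry(start_deg=60.5)
        noise = sp.NoiseSpec(dark_sd=1.0, shot_sd=0.01, seed=7)
        raw = sp.synthesize_image_set(water_stack, geom, n_rows=100, noise=noise, scale=1000.0)
        curve = sp.extract_curve(sp.normalize_images(raw), row_band=(0, 99), geometry=geom)
        # per-pixel ratio sd propagated from shot + dark noise, averaged over rows
        te_clean = 1000.0 * sp.fresnel_reflectance(water_stack, geom.angles(), "TE")
        tm_clean = 1000.0 * sp.fresnel_reflectance(water_stack, geom.angles(), "TM")
        var_tm = (0.01 * tm_clean) ** 2 + 2.0  # shot^2 + dark-noise on frame & dark
        var_te = (0.01 * te_clean) ** 2 + 2.0
        ratio = tm_clean / te_clean
        sd = np.sqrt(var_tm / te_clean**2 + (ratio / te_clean) ** 2 * var_te) / np.sqrt(100)
        z = np.abs(curve.values - water_curve.values) / sd
        # 3-sigma per pixel plus a max-order-statistic allowance over 1280 pixels
        assert np.mean(z <= 3.0) >= 0.99
        assert np.max(z) <= 6.0

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            sp.NoiseSpec(dark_sd=-1.0)

    def test_invalid_rows_rejected(self, water_stack, water_geometry):
        with pytest.raises(ValueError):
            sp.synthesize_image_set(water_stack, water_geometry, n_rows=0)


class TestOpticalStackValidation:
    def test_prism_must_exceed_bulk(self):
        with pytest.raises(ValueError):
            sp.OpticalStack(prism_index=1.3, layers=(), bulk_index=1.4)

    def test_layer_thickness_positive(self):
        with pytest.raises(ValueError):
            sp.OpticalStack(prism_index=1.5, layers=((GOLD_INDEX_770NM, -5.0),), bulk_index=1.0)

    def test_wavelength_positive(self):
        with pytest.raises(ValueError):
            sp.OpticalStack(prism_index=1.5, layers=(), bulk_index=1.0, wavelength_nm=0.0)

    def test_default_metals_are_absorbing(self):
        assert GOLD_INDEX_770NM.imag > 0
        assert CHROMIUM_INDEX_770NM.imag > 0
        # gold permittivity reproduces the handbook default
        eps = GOLD_INDEX_770NM**2
        assert eps.real == pytest.approx(-20.5, abs=1e-9)
        assert eps.imag == pytest.approx(1.4, abs=1e-9)
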