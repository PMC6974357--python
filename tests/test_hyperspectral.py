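"""Reflectance calibration and fourth-derivative pigment mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

import farredo2 as f2
from farredo2.types import DimensionError


def flat_cube(wl, values, shape=(4, 5), kind="raw"):
    """Cube whose every pixel carries the same spectrum ``values``."""
    values = np.broadcast_to(np.asarray(values, float)[:, None, None],
                             (len(wl),) + shape).copy()
    return f2.SpectralCube(wl, values, kind=kind)


WL = np.arange(400.0, 850.0 + 1, 2.0)


class TestDarkCorrect:
    def test_identity_and_offset(self):
        raw = flat_cube(WL, np.linspace(100, 200, WL.size))
        assert np.all(f2.dark_correct(raw, raw).data == 0.0)
        plus5 = f2.SpectralCube(WL, raw.data + 5.0)
        assert np.allclose(f2.dark_correct(plus5, raw).data, 5.0)

    def test_clips_below_dark_at_zero(self):
        raw = flat_cube(WL, np.full(WL.size, 100.0))
        dark = flat_cube(WL, np.full(WL.size, 90.0))
        raw.data[10, 2, 3] = 50.0  # one pixel below dark
        out = f2.dark_correct(raw, dark)
        assert out.data[10, 2, 3] == 0.0
        assert np.allclose(np.delete(out.data[10], 2 * 5 + 3), 10.0)

    def test_shape_mismatch_raises(self):
        raw = flat_cube(WL, np.full(WL.size, 1.0))
        dark = flat_cube(WL[:-1], np.full(WL.size - 1, 1.0))
        with pytest.raises(DimensionError):
            f2.dark_correct(raw, dark)


class TestToReflectance:
    def test_sample_equal_to_standard_gives_standard_pct(self):
        std = flat_cube(WL, np.linspace(500, 1500, WL.size), kind="dark_corrected")
        out = f2.to_reflectance(std, std, standard_pct=20.0)
        assert np.allclose(out.data, 20.0)
        out2 = f2.to_reflectance(
            f2.SpectralCube(WL, 2 * std.data, kind="dark_corrected"), std
        )
        assert np.allclose(out2.data, 40.0)

    def test_forward_model_round_trip(self, default_scene, default_reflectance):
        """Reconstructing % reflectance through the acquisition model is the
        identity on noiseless generator scenes."""
        err = np.nanmax(np.abs(default_reflectance.data
                               - default_scene.reflectance_true.data))
        assert err < 1e-6

    def test_zero_reference_band_masked(self):
        std = flat_cube(WL, np.full(WL.size, 100.0), kind="dark_corrected")
        std.data[3] = 0.0
        with pytest.warns(RuntimeWarning, match="zero signal"):
            out = f2.to_reflectance(std, std)
        assert np.all(np.isnan(out.data[3]))
        assert np.allclose(out.data[4], 20.0)


class TestRgbComposite:
    def test_channels_equal_planes_up_to_scale(self, default_reflectance):
        rgb = f2.rgb_composite(default_reflectance)
        for ch, nm in (("red", 650), ("green", 550), ("blue", 450)):
            fac = rgb.scale[ch]["factor"]
            assert rgb.scale[ch]["wavelength_nm"] == nm
            assert np.allclose(getattr(rgb, ch), default_reflectance.plane(nm) * fac)

    def test_flat_cube_is_gray(self):
        cube = flat_cube(WL, np.full(WL.size, 30.0), kind="reflectance")
        rgb = f2.rgb_composite(cube)
        assert np.allclose(rgb.red, rgb.green)
        assert np.allclose(rgb.green, rgb.blue)

    def test_nearest_band_selection_and_tolerance(self):
        cube = flat_cube(WL, np.linspace(10, 50, WL.size), kind="reflectance")
        rgb = f2.rgb_composite(cube, r=651.0)  # 2-nm grid → snaps to 650
        assert rgb.scale["red"]["wavelength_nm"] == 650.0
        with pytest.raises(ValueError, match="no sampled band"):
            f2.rgb_composite(cube, r=860.0)


class TestFourthDerivative:
    def test_annihilates_cubic_baselines(self):
        """Degree-≤3 spectra vanish exactly (up to float rounding), for any
        valid window/polyorder — the baseline-suppression rationale."""
        coeffs = [3.0, 0.05, -2e-4, 1.5e-7]
        spec = np.polynomial.polynomial.polyval(WL, coeffs)
        cube = flat_cube(WL, spec, kind="reflectance")
        for window, polyorder in [(9, 5), (25, 5), (13, 6), (17, 8)]:
            d = f2.spectral_fourth_derivative(cube, window=window, polyorder=polyorder)
            assert np.nanmax(np.abs(d.data)) < 1e-9

    def test_quartic_gives_constant_24(self):
        cube = flat_cube(WL, WL**4, kind="reflectance")
        d = f2.spectral_fourth_derivative(cube, window=9, polyorder=5)
        # catastrophic cancellation at λ⁴ ~ 1e11 leaves ~1e-4 absolute noise
        assert np.nanmax(np.abs(d.data - 24.0)) < 1e-3

    def test_gaussian_dip_matches_analytic_profile(self):
        """On a grid that resolves the dip, the filter reproduces the
        closed-form 4th derivative of a Gaussian; the (negated) profile
        peaks exactly at the dip center."""
        wl = np.arange(400.0, 850.0 + 0.5, 1.0)
        sigma, center, depth, base = 12.0, 720.0, 0.4, 30.0
        spec = base * (1.0 - depth * np.exp(-((wl - center) ** 2) / (2 * sigma**2)))
        cube = flat_cube(wl, spec, shape=(2, 2), kind="reflectance")
        d = f2.spectral_fourth_derivative(cube, window=9, polyorder=5)
        x = (wl - center) / sigma
        analytic = -base * depth * (x**4 - 6 * x**2 + 3) / sigma**4 * np.exp(-(x**2) / 2)
        prof = d.data[:, 0, 0]
        ok = np.isfinite(prof)
        sup = np.max(np.abs(prof[ok] - analytic[ok]))
        assert sup <= 0.05 * np.max(np.abs(analytic))
        assert wl[np.nanargmin(np.where(ok, prof, np.inf))] == center

    def test_edges_masked_and_preconditions(self):
        cube = flat_cube(WL, np.full(WL.size, 1.0), kind="reflectance")
        d = f2.spectral_fourth_derivative(cube, window=9)
        assert np.all(np.isnan(d.data[:4])) and np.all(np.isnan(d.data[-4:]))
        assert np.all(np.isfinite(d.data[4:-4]))
        with pytest.raises(ValueError):
            f2.spectral_fourth_derivative(cube, window=9, polyorder=3)
        with pytest.raises(ValueError):
            f2.spectral_fourth_derivative(flat_cube(WL[:5], np.ones(5)), window=9)


class TestBandAmplitude:
    def test_zero_derivative_gives_zero_map(self):
        cube = flat_cube(WL, np.full(WL.size, 25.0), kind="reflectance")
        d = f2.spectral_fourth_derivative(cube)
        amp = f2.band_amplitude_map(d, f2.CHLF_BAND)
        assert np.allclose(amp.data, 0.0, atol=1e-12)

    def test_rank_recovery_is_exact_on_separated_abundances(self):
        """Amplitude is linear in dip depth, so the recovered map ranks
        pixels exactly like the true abundance field (noiseless)."""
        h, w = 48, 48
        rng = np.random.default_rng(7)
        field = rng.permutation(np.linspace(0.1, 1.0, h * w)).reshape(h, w)
        sc = f2.synth_hyperspectral_scene(f2.SceneParams(
            shape=(h, w),
            pigments=(f2.PigmentSpec("chlf", 720.0, 8.0, 0.4, field),),
        ))
        refl = f2.to_reflectance(f2.dark_correct(sc.raw, sc.dark),
                                 f2.dark_correct(sc.standard, sc.standard_dark))
        maps = f2.pigment_maps(refl)
        rho = spearmanr(maps.chlf.data.ravel(), sc.truth["chlf"].data.ravel()).statistic
        assert rho == 1.0

    def test_band_separation_between_pigments(self):
        """A chl-a-only scene leaves the chl-f window essentially empty."""
        sc = f2.synth_hyperspectral_scene(f2.SceneParams(
            pigments=(f2.PigmentSpec("chla", 675.0, 8.0, 0.6,
                                     f2.LayerLayout((0.0, 0.5), 1.0)),),
        ))
        refl = f2.to_reflectance(f2.dark_correct(sc.raw, sc.dark),
                                 f2.dark_correct(sc.standard, sc.standard_dark))
        maps = f2.pigment_maps(refl)
        assert np.nanmax(maps.chla.data) > 0
        assert np.nanmax(maps.chlf.data) < 0.05 * np.nanmax(maps.chla.data)

    def test_band_outside_range_raises(self, default_reflectance):
        d = f2.spectral_fourth_derivative(default_reflectance)
        with pytest.raises(ValueError):
            f2.band_amplitude_map(d, f2.BandWindow(900.0, 910.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c0=st.floats(-5, 5), c1=st.floats(-0.05, 0.05),
           c2=st.floats(-1e-4, 1e-4), c3=st.floats(-1e-7, 1e-7))
    def test_invariant_under_cubic_baseline_shift(self, c0, c1, c2, c3):
        """Adding any degree-≤3 baseline to all spectra leaves the band
        amplitude map unchanged — the point of derivative spectroscopy."""
        wl = WL
        dip = 10.0 * np.exp(-((wl - 720.0) ** 2) / (2 * 8.0**2))
        spec = 40.0 - dip
        shift = np.polynomial.polynomial.polyval(wl, [c0, c1, c2, c3])
        a = f2.band_amplitude_map(
            f2.spectral_fourth_derivative(flat_cube(wl, spec, (2, 2), "reflectance")),
            f2.CHLF_BAND).data
        b = f2.band_amplitude_map(
            f2.spectral_fourth_derivative(flat_cube(wl, spec + shift, (2, 2), "reflectance")),
            f2.CHLF_BAND).data
        assert np.allclose(a, b, atol=1e-8)


class TestNormalizeAbundance:
    def test_constant_map_becomes_ones_and_zero_stays_zero(self):
        ones = f2.normalize_abundance(f2.ScalarImage(np.full((4, 4), 3.7)))
        assert np.all(ones.data == 1.0)
        zeros = f2.normalize_abundance(f2.ScalarImage(np.zeros((4, 4))))
        assert np.all(zeros.data == 0.0)

    def test_linear_scaling_with_full_clip(self):
        img = f2.ScalarImage(np.array([[0.0, 1.0, 2.0, 3.0, 100.0]]))
        out = f2.normalize_abundance(img, clip_pct=100.0)
        assert np.allclose(out.data, [[0.0, 0.01, 0.02, 0.03, 1.0]])

    def test_clip_saturates_hot_pixels(self):
        data = np.linspace(0, 1, 1000).reshape(10, 100).copy()
        data[0, 0] = 1e6
        out = f2.normalize_abundance(f2.ScalarImage(data), clip_pct=99.5)
        assert out.data[0, 0] == 1.0
        assert np.all((out.data >= 0) & (out.data <= 1))
        # order preserved below the clip point
        flat = out.data.ravel()[1:900]
        assert np.all(np.diff(flat) >= 0)


class TestPigmentOverlay:
    def _rgb(self, shape=(8, 8)):
        g = np.linspace(0.2, 0.8, shape[0] * shape[1]).reshape(shape)
        return f2.RGBFrame(g, g, g)

    def _maps(self, chla, chlf):
        rel = f2.normalize_abundance(f2.ScalarImage(chlf))
        return f2.PigmentMaps(f2.ScalarImage(chla), f2.ScalarImage(chlf), rel)

    def test_zero_maps_return_input(self):
        rgb = self._rgb()
        maps = self._maps(np.zeros((8, 8)), np.zeros((8, 8)))
        out = f2.pigment_overlay(rgb, maps, 0.5, 0.5)
        assert np.array_equal(out.stack(), rgb.stack())

    def test_hotspot_mask_rendered_red_and_precedence(self):
        rgb = self._rgb()
        chla = np.ones((8, 8))  # everywhere above threshold → green
        chlf = np.zeros((8, 8))
        chlf[2:4, 5:7] = 1.0  # hotspot → red, overriding green
        out = f2.pigment_overlay(rgb, self._maps(chla, chlf), 0.5, 0.5)
        hot = np.zeros((8, 8), bool)
        hot[2:4, 5:7] = True
        assert np.all(out.stack()[hot] == (1.0, 0.0, 0.0))
        assert np.all(out.stack()[~hot] == (0.0, 1.0, 0.0))

    def test_continuous_mode_blends_only_above_threshold(self):
        rgb = self._rgb()
        chlf = np.zeros((8, 8))
        chlf[5, 5] = 1.0
        out = f2.pigment_overlay(rgb, self._maps(np.zeros((8, 8)), chlf),
                                 0.5, 0.5, mode="continuous")
        assert not np.array_equal(out.stack()[5, 5], rgb.stack()[5, 5])
        assert np.array_equal(out.stack()[0, 0], rgb.stack()[0, 0])

    def test_shape_mismatch_raises(self):
        with pytest.raises(DimensionError):
            f2.pigment_overlay(self._rgb((4, 4)),
                               self._maps(np.zeros((8, 8)), np.zeros((8, 8))), 0.5, 0.5)


class TestRoiSpectrum:
    def test_single_pixel_and_uniform(self, default_reflectance):
        roi = np.zeros(default_reflectance.image_shape, bool)
        roi[3, 4] = True
        wl, mean, sd = f2.extract_roi_spectrum(default_reflectance, roi)
        assert np.allclose(mean, default_reflectance.data[:, 3, 4])
        assert np.all(sd == 0.0)

    def test_two_pixel_mean(self):
        cube = flat_cube(WL, np.full(WL.size, 1.0))
        cube.data[:, 0, 0] = 2.0
        cube.data[:, 0, 1] = 4.0
        roi = np.zeros(cube.image_shape, bool)
        roi[0, :2] = True
        _, mean, sd = f2.extract_roi_spectrum(cube, roi)
        assert np.allclose(mean, 3.0)
        assert np.allclose(sd, 1.0)  # population SD of {2, 4}

    def test_empty_roi_raises(self, default_reflectance):
        with pytest.raises(ValueError, match="empty"):
            f2.extract_roi_spectrum(default_reflectance,
                                    np.zeros(default_reflectance.image_shape, bool))


class TestEmissionBandMap:
    def test_single_band_emission_is_pure_color(self):
        wl = np.arange(500.0, 760.0, 10.0)
        data = np.zeros((wl.size, 6, 6))
        sel = (wl >= 740) & (wl <= 750)
        data[sel, 2:4, 2:4] = 100.0
        fluor = f2.SpectralCube(wl, data, kind="fluorescence")
        rgb = f2.emission_band_map(fluor, [
            (f2.BandWindow(650, 660), "blue"),
            (f2.BandWindow(690, 700), "green"),
            (f2.BandWindow(740, 750), "red"),
        ])
        assert rgb.red[2, 2] == 1.0
        assert np.all(rgb.green == 0.0) and np.all(rgb.blue == 0.0)

    def test_two_population_scene_separates_channels(self):
        """Populations emitting in disjoint bands map to disjoint channels."""
        wl = np.arange(500.0, 760.0, 10.0)
        data = np.zeros((wl.size, 6, 6))
        data[(wl >= 690) & (wl <= 700), :3, :] = 50.0  # chl-a-like, top half
        data[(wl >= 740) & (wl <= 750), 3:, :] = 80.0  # far-red, bottom half
        fluor = f2.SpectralCube(wl, data, kind="fluorescence")
        rgb = f2.emission_band_map(fluor, [
            (f2.BandWindow(690, 700), "green"),
            (f2.BandWindow(740, 750), "red"),
        ])
        assert np.all(rgb.green[:3] == 1.0) and np.all(rgb.green[3:] == 0.0)
        assert np.all(rgb.red[3:] == 1.0) and np.all(rgb.red[:3] == 0.0)

    def test_requires_fluorescence_kind(self, default_reflectance):
        with pytest.raises(ValueError, match="fluorescence"):
            f2.emission_band_map(default_reflectance, [(f2.BandWindow(650, 660), "red")])
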