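"""Cauchy-Lorentz band synthesis and illuminant optimization."""

import numpy as np
import pytest

from savehsi.colorspace import DomainError
from savehsi.enhance import (
    CauchyBand,
    EnhancementProfile,
    build_illuminant,
    cauchy_lorentz,
    default_bounds,
    enhance_image,
    load_profile,
    make_target_palette,
    objective,
    optimize_illuminant,
    patch_colors_under_light,
    save_profile,
)
from savehsi.synthetic import REFERENCE_NBI_BANDS, SceneSpec, make_endoscopy_scene


def _true_params():
    return np.array([(b.x0, b.gamma, b.amplitude) for b in REFERENCE_NBI_BANDS]).ravel()


class TestCauchyLorentz:
    def test_peak_value(self):
        assert cauchy_lorentz(500.0, 500.0, 10.0) == pytest.approx(1 / (10 * np.pi), abs=1e-12)

    def test_half_width_at_half_maximum(self):
        peak = cauchy_lorentz(500.0, 500.0, 15.0)
        assert cauchy_lorentz(515.0, 500.0, 15.0) == pytest.approx(peak / 2)
        assert cauchy_lorentz(485.0, 500.0, 15.0) == pytest.approx(peak / 2)

    def test_tail_mass_closed_form(self):
        # integral over +-1000 gamma equals (2/pi) arctan(1000)
        gamma = 7.0
        x = np.linspace(-1000 * gamma, 1000 * gamma, 2_000_001)
        mass = np.trapezoid(cauchy_lorentz(x, 0.0, gamma), x)
        assert mass == pytest.approx((2 / np.pi) * np.arctan(1000.0), abs=1e-6)

    def test_symmetry(self):
        x = np.linspace(-50, 50, 101)
        v = cauchy_lorentz(x + 600, 600.0, 9.0)
        assert np.allclose(v, v[::-1])

    def test_invalid_gamma(self):
        with pytest.raises(DomainError):
            cauchy_lorentz(500.0, 500.0, 0.0)


class TestBuildIlluminant:
    def test_single_band_peaks_at_center(self, grid):
        illum = build_illuminant([CauchyBand(540.0, 10.0, 0.7)], grid)
        assert grid.wavelengths[np.argmax(illum.values)] == 540.0
        assert illum.values.max() == pytest.approx(1.0)
        assert illum.values.min() > 0.0  # heavy tails keep it positive

    def test_duplicate_band_normalisation_cancels(self, grid):
        one = build_illuminant([CauchyBand(415.0, 12.0, 0.5)], grid)
        two = build_illuminant([CauchyBand(415.0, 12.0, 0.5)] * 2, grid)
        assert np.allclose(one.values, two.values)

    def test_two_bands_local_maxima(self, grid):
        illum = build_illuminant(
            [CauchyBand(415.0, 15.0, 1.0), CauchyBand(540.0, 15.0, 0.8)], grid
        )
        v = illum.values
        for peak in (415.0, 540.0):
            i = grid.index_of(peak)
            assert v[i] > v[i - 2] and v[i] > v[i + 2]

    def test_empty_bands_rejected(self, grid):
        with pytest.raises(DomainError):
            build_illuminant([], grid)


class TestPatchColors:
    def test_neutral_patch_is_achromatic_under_any_light(self, grid, cmf, nbi_light):
        gray = np.full(grid.n_samples, 0.5)
        lab = patch_colors_under_light(gray, nbi_light, cmf)[0]
        assert abs(lab[1]) < 1e-9 and abs(lab[2]) < 1e-9

    def test_unit_patch_is_white(self, grid, cmf, nbi_light):
        lab = patch_colors_under_light(np.ones(grid.n_samples), nbi_light, cmf)[0]
        assert np.allclose(lab, [100.0, 0.0, 0.0], atol=1e-9)

    def test_red_reflector_is_dark_under_violet_light(self, grid, cmf, wli_light):
        violet = build_illuminant([CauchyBand(415.0, 8.0, 1.0)], grid)
        red = 0.05 + 0.9 / (1.0 + np.exp(-(grid.wavelengths - 600) / 15))
        l_violet = patch_colors_under_light(red, violet, cmf)[0][0]
        l_daylight = patch_colors_under_light(red, wli_light, cmf)[0][0]
        assert l_violet < 45.0
        assert l_violet < l_daylight - 10.0


class TestObjective:
    def test_zero_at_generating_light(self, checker_values, nbi_light, grid, cmf):
        target = make_target_palette(checker_values, nbi_light, cmf)
        assert objective(_true_params(), checker_values, target, grid, cmf) < 1e-9

    def test_non_negative_everywhere(self, checker_values, nbi_light, grid, cmf):
        target = make_target_palette(checker_values, nbi_light, cmf)
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.uniform([395, 2, 0] * 5, [800, 60, 1] * 5)
            assert objective(p, checker_values, target, grid, cmf) >= 0.0

    def test_perturbed_center_is_worse(self, checker_values, nbi_light, grid, cmf):
        target = make_target_palette(checker_values, nbi_light, cmf)
        p = _true_params()
        p[0] += 1.0  # shift the 415 nm band by 1 nm
        assert objective(p, checker_values, target, grid, cmf) > 0.0

    def test_invalid_params_penalised_not_raised(self, checker_values, nbi_light, grid, cmf):
        target = make_target_palette(checker_values, nbi_light, cmf)
        bad_gamma = _true_params()
        bad_gamma[1] = -5.0
        zero_amp = _true_params()
        zero_amp[2::3] = 0.0
        for p in (bad_gamma, zero_amp, np.full(15, np.nan)):
            val = objective(p, checker_values, target, grid, cmf)
            assert np.isfinite(val) and val >= 1e5


class TestOptimize:
    @pytest.fixture()
    def target(self, checker_values, nbi_light, cmf):
        return make_target_palette(checker_values, nbi_light, cmf)

    def test_recovers_generating_light(self, checker_values, target, grid, cmf):
        profile = optimize_illuminant(checker_values, target, grid, cmf,
                                      seed=0, max_iter=150)
        assert profile.objective_value < 1.0

    def test_same_seed_same_result(self, checker_values, target, grid, cmf):
        a = optimize_illuminant(checker_values, target, grid, cmf, seed=3, max_iter=30)
        b = optimize_illuminant(checker_values, target, grid, cmf, seed=3, max_iter=30)
        assert a.optimizer_trace == b.optimizer_trace
        assert np.array_equal(
            [x.x0 for x in a.bands], [x.x0 for x in b.bands]
        )

    def test_trace_monotone_non_increasing(self, checker_values, target, grid, cmf):
        p = optimize_illuminant(checker_values, target, grid, cmf, seed=1, max_iter=50)
        assert all(a >= b for a, b in zip(p.optimizer_trace, p.optimizer_trace[1:]))

    def test_zero_budget_returns_initial_guess(self, checker_values, target, grid, cmf):
        p = optimize_illuminant(checker_values, target, grid, cmf, seed=0, max_iter=0)
        bounds = default_bounds()
        mid = np.array([(lo + hi) / 2 for lo, hi in bounds]).reshape(-1, 3)
        assert np.allclose([b.x0 for b in p.bands], mid[:, 0])
        assert p.objective_value == pytest.approx(
            objective(mid.ravel(), checker_values, target, grid, cmf)
        )

    def test_never_worse_than_initial_guess(self, checker_values, target, grid, cmf):
        init = optimize_illuminant(checker_values, target, grid, cmf, seed=0, max_iter=0)
        run = optimize_illuminant(checker_values, target, grid, cmf, seed=0, max_iter=20)
        assert run.objective_value <= init.objective_value + 1e-12

    def test_empty_bounds_rejected(self, checker_values, target, grid, cmf):
        with pytest.raises(DomainError):
            optimize_illuminant(checker_values, target, grid, cmf, bounds=[], seed=0)


class TestEnhanceImage:
    def test_identity_relight_approximates_input(self, model, camera, wli_light, cmf):
        img, _, _ = make_endoscopy_scene(SceneSpec(seed=5, height=32, width=32,
                                                   lesion_radius=8), camera, wli_light, cmf)
        profile = EnhancementProfile(
            bands=[CauchyBand(550.0, 200.0, 1.0)],
            illuminant=wli_light, objective_value=0.0,
        )
        out = enhance_image(img, model, profile)
        err = np.mean(np.abs(out.astype(float) - img.astype(float)))
        assert err < 15.0  # camera is not colorimetric; see exact-camera test

    def test_identity_relight_exact_camera(self, grid, cmf, wli_light, exact_camera):
        from savehsi.calibration import calibrate
        from savehsi.synthetic import make_checker_measurements

        ms = make_checker_measurements(0, exact_camera, wli_light, cmf)
        model = calibrate(ms, wli_light, cmf)
        img, _, _ = make_endoscopy_scene(SceneSpec(seed=5, height=32, width=32,
                                                   lesion_radius=8),
                                         exact_camera, wli_light, cmf)
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
        profile = EnhancementProfile(
            bands=[CauchyBand(550.0, 200.0, 1.0)],
            illuminant=wli_light, objective_value=0.0,
        )
        out = enhance_image(img, model, profile)
        assert np.mean(np.abs(out.astype(float) - img.astype(float))) < 5.0

    def test_uniform_image_stays_uniform(self, model, nbi_light, cmf):
        profile = EnhancementProfile(
            bands=list(REFERENCE_NBI_BANDS), illuminant=nbi_light, objective_value=0.0
        )
        img = np.full((6, 6, 3), [180, 90, 80], dtype=np.uint8)
        out = enhance_image(img, model, profile)
        assert np.all(out == out[0, 0])

    def test_equal_pixels_map_equally(self, model, nbi_light):
        profile = EnhancementProfile(
            bands=list(REFERENCE_NBI_BANDS), illuminant=nbi_light, objective_value=0.0
        )
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, (10, 10, 3), dtype=np.uint8)
        img[2, 3] = img[7, 8]
        out = enhance_image(img, model, profile)
        assert np.array_equal(out[2, 3], out[7, 8])


class TestProfileSerialisation:
    def test_json_round_trip(self, grid, nbi_light, tmp_path):
        profile = EnhancementProfile(
            bands=list(REFERENCE_NBI_BANDS),
            illuminant=nbi_light,
            objective_value=0.25,
            optimizer_trace=[1.0, 0.5, 0.25],
            seed=7,
        )
        save_profile(profile, tmp_path / "p.json")
        back = load_profile(tmp_path / "p.json")
        assert back.seed == 7
        assert back.optimizer_trace == [1.0, 0.5, 0.25]
        assert np.allclose(back.illuminant.values, profile.illuminant.values)
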