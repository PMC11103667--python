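"""LP test object, texture generator and image-quality metrics."""

import numpy as np
import pytest

from dbtblur.blur import BlurOperator
from dbtblur.kernel import discretize_kernel
from dbtblur.metrics import lp_contrast, noise_rms, structural_nps
from dbtblur.phantoms import (
    LPObjectSpec,
    bar_intervals,
    make_lp_object,
    make_texture_phantom,
    render_lp_slice,
    space_intervals,
)


class TestLPObject:
    def test_bar_count_and_area(self):
        """4 frequency groups × 5 columns × 5 bars = 100 bars; the fine-grid
        total area matches the analytic layout area."""
        spec = LPObjectSpec()
        obj = make_lp_object(spec)
        expected_area = sum(
            (hi - lo) * spec.bar_length
            for g in range(4)
            for c in range(5)
            for lo, hi in bar_intervals(spec, g, c)
        )
        n_bars = sum(
            len(bar_intervals(spec, g, c)) for g in range(4) for c in range(5)
        )
        assert n_bars == 100
        measured_area = obj.sum() / spec.bar_attenuation * spec.fine_voxel**2
        assert measured_area == pytest.approx(expected_area, rel=1e-6)

    def test_frequencies(self):
        spec = LPObjectSpec()
        np.testing.assert_allclose(
            spec.frequencies, [5.0, 1 / 0.3, 2.5, 2.0], rtol=1e-12
        )
        np.testing.assert_allclose(
            spec.frequencies, 1.0 / (2.0 * np.asarray(spec.bar_widths))
        )

    def test_column_shift_accumulates(self):
        spec = LPObjectSpec()
        b0 = bar_intervals(spec, 0, 0)[0][0]
        b3 = bar_intervals(spec, 0, 3)[0][0]
        assert b3 - b0 == pytest.approx(3 * spec.column_shift)

    def test_spaces_between_bars(self):
        spec = LPObjectSpec()
        bars = bar_intervals(spec, 2, 1)
        spaces = space_intervals(spec, 2, 1)
        assert len(spaces) == len(bars) - 1
        for (b_lo, b_hi), (s_lo, s_hi) in zip(bars, spaces):
            assert s_lo == pytest.approx(b_hi)
            assert s_hi - s_lo == pytest.approx(b_hi - b_lo)

    def test_layout_overflow_rejected(self):
        with pytest.raises(ValueError):
            LPObjectSpec(extent=20.0)


class TestLPContrast:
    def test_ideal_rendering_scores_one(self, lp_scene):
        spec = lp_scene.spec
        ideal = render_lp_slice(
            spec, lp_scene.pixel, shape=lp_scene.x_blur.shape,
            magnification=lp_scene.magnification,
        )
        cr = lp_contrast(
            ideal, spec, lp_scene.pixel, magnification=lp_scene.magnification,
            bar_amplitude=spec.bar_attenuation * spec.thickness,
        )
        np.testing.assert_allclose(cr.contrast, 1.0, atol=1e-9)

    def test_constant_image_scores_zero(self, lp_scene):
        img = np.full(lp_scene.x_blur.shape, 5.0)
        cr = lp_contrast(img, lp_scene.spec, lp_scene.pixel,
                         magnification=lp_scene.magnification)
        np.testing.assert_allclose(cr.contrast, 0.0, atol=1e-12)

    def test_full_period_averaging_kills_contrast(self):
        """Blurring with a rect spanning one full LP period zeroes the
        contrast of that frequency (analytic averaging)."""
        spec = LPObjectSpec()
        ideal = render_lp_slice(spec, 0.085)
        period = 2 * spec.bar_widths[-1]  # 2 LP/mm group
        op = BlurOperator([discretize_kernel(period, 0.085)], ideal.shape[1])
        cr = lp_contrast(op.apply(ideal), spec, 0.085,
                         bar_amplitude=spec.bar_attenuation * spec.thickness)
        assert abs(cr.contrast[-1]) < 0.03

    def test_affine_intensity_invariance(self, lp_scene):
        """Contrast is invariant under x → a·x + b when the amplitude is
        scaled by the same gain."""
        rng = np.random.default_rng(0)
        img = lp_scene.x_blur
        base = lp_contrast(img, lp_scene.spec, lp_scene.pixel,
                           magnification=lp_scene.magnification,
                           bar_amplitude=lp_scene.bar_amplitude)
        for a, b in [(3.0, 1.0), (-0.5, 2.0), (0.02, -7.0)]:
            mapped = lp_contrast(a * img + b, lp_scene.spec, lp_scene.pixel,
                                 magnification=lp_scene.magnification,
                                 bar_amplitude=a * lp_scene.bar_amplitude)
            np.testing.assert_allclose(mapped.contrast, base.contrast, rtol=1e-9)

    def test_contrast_decreases_with_kernel_length(self):
        """Longer source-motion kernels strictly reduce contrast at every
        LP frequency."""
        spec = LPObjectSpec()
        ideal = render_lp_slice(spec, 0.085)
        amp = spec.bar_attenuation * spec.thickness
        prev = None
        # restrict to 2-3.33 LP/mm, which stay above their first contrast
        # zero for these lengths (beyond it the square-wave response
        # oscillates in sign)
        for w in (0.0, 0.10, 0.15, 0.20, 0.25):
            op = BlurOperator([discretize_kernel(w, 0.085)], ideal.shape[1])
            c = lp_contrast(op.apply(ideal), spec, 0.085, bar_amplitude=amp).contrast
            assert np.all(c[1:] > 0)
            if prev is not None:
                assert np.all(c[1:] < prev[1:] + 1e-12)
            prev = c


class TestNoiseRms:
    def test_quadratic_surface_gives_zero(self):
        i, j = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        img = 3.0 + 0.1 * i - 0.2 * j + 0.01 * i * i + 0.005 * i * j - 0.02 * j * j
        res = noise_rms(img, [(10, 10), (20, 25)])
        assert res.mean == pytest.approx(0.0, abs=1e-8)

    def test_constant_image_gives_zero(self):
        res = noise_rms(np.full((30, 30), 7.0), [(15, 15)])
        assert res.mean == pytest.approx(0.0, abs=1e-10)

    def test_white_noise_residual_dof_oracle(self):
        """White noise σ=1: detrended RMS ≈ √(94/100) from the residual
        degrees of freedom (100 pixels − 6 quadratic coefficients)."""
        rng = np.random.default_rng(0)
        img = rng.standard_normal((400, 400))
        centers = [(i, j) for i in range(10, 390, 20) for j in range(10, 390, 20)]
        res = noise_rms(img, centers)
        assert res.mean == pytest.approx(np.sqrt(94 / 100), abs=0.01)

    def test_out_of_bounds_roi_rejected(self):
        with pytest.raises(ValueError):
            noise_rms(np.zeros((20, 20)), [(2, 10)])


class TestTexturePhantom:
    def test_same_seed_reproducible(self):
        a = make_texture_phantom((64, 64), 3.0, 0.01, seed=5)
        b = make_texture_phantom((64, 64), 3.0, 0.01, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_mean_and_amplitude(self):
        f = make_texture_phantom((128, 128), 3.0, 0.02, seed=1, mean=0.05)
        assert f.mean() == pytest.approx(0.05, abs=1e-6)
        assert f.std() == pytest.approx(0.02, rel=1e-6)

    def test_beta_zero_is_white(self):
        imgs = [make_texture_phantom((128, 128), 0.0, 1.0, seed=s, mean=0.0)
                for s in range(6)]
        r = structural_nps(imgs)
        assert abs(r.exponent) < 0.15

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            make_texture_phantom((8, 8), -1.0, 1.0, seed=0)


class TestStructuralNps:
    @pytest.mark.parametrize("beta", [2.0, 3.0, 4.0])
    def test_generator_roundtrip_recovers_exponent(self, beta):
        imgs = [make_texture_phantom((256, 256), beta, 1.0, seed=s, mean=0.0)
                for s in range(10)]
        r = structural_nps(imgs, pixel_mm=0.085)
        assert r.exponent == pytest.approx(beta, abs=0.3)

    def test_intensity_scaling_moves_power_not_exponent(self):
        imgs = [make_texture_phantom((128, 128), 3.0, 1.0, seed=s, mean=0.0)
                for s in range(4)]
        r1 = structural_nps(imgs)
        r2 = structural_nps([3.0 * im for im in imgs])
        assert r2.exponent == pytest.approx(r1.exponent, abs=1e-9)
        np.testing.assert_allclose(r2.power, 9.0 * r1.power, rtol=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            structural_nps([])
        with pytest.raises(ValueError):
            structural_nps([np.zeros((1, 1))])
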