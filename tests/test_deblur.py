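"""Posterior-sampling deblurrer and classical baselines."""

import numpy as np
import pytest

from dbtblur.blur import BlurOperator
from dbtblur.deblur import (
    PosteriorConfig,
    deblur_posterior,
    deblur_volume,
    tikhonov_deblur,
    tv_deblur,
)
from dbtblur.diffusion import ddim_sample, forward_diffuse, make_schedule
from dbtblur.kernel import BlurKernelSpec, discretize_kernel


def _identity_op(n):
    return BlurOperator([BlurKernelSpec(0.0, 0.0, np.array([1.0]))], n)


def _rect_op(length, n, pixel=0.085):
    return BlurOperator([discretize_kernel(length, pixel)], n)


class TestPosterior:
    def test_lambda_zero_is_unconditional_ddim(self, schedule):
        """With λ=0 the update is exactly T̄ unconditional DDIM steps from
        the same starting point."""
        rng = np.random.default_rng(0)
        x_blur = rng.standard_normal((6, 6))
        op = _rect_op(0.3, 6)

        def den(x, t):
            # arbitrary but deterministic nonlinear noise predictor
            return 0.1 * np.tanh(x) + 0.01 * t / schedule.T

        t_bar = 7
        noise = np.random.default_rng(3).standard_normal(x_blur.shape)
        x_T = forward_diffuse(x_blur, t_bar, schedule, noise)
        out = deblur_posterior(
            x_blur, op, den, schedule,
            PosteriorConfig(lam=0.0, t_bar=t_bar), x_T=x_T,
        )
        expected = ddim_sample(den, schedule, x_T, steps=range(t_bar, 0, -1))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_single_step_hand_algebra(self, schedule):
        """B = I, ε_θ ≡ 0, one step from t=1 on a 2×2 image:
        x0 = x_1/√ᾱ_1 − λ·(x_1 − x_blur), checked by hand."""
        x_blur = np.array([[1.0, -2.0], [0.5, 3.0]])
        x_1 = np.array([[0.2, 0.4], [-0.6, 1.0]])
        lam = 0.4
        op = _identity_op(2)
        out = deblur_posterior(
            x_blur, op, lambda x, t: np.zeros_like(x), schedule,
            PosteriorConfig(lam=lam, t_bar=1), x_T=x_1,
        )
        expected = x_1 / np.sqrt(schedule.alpha_bar(1)) - lam * (x_1 - x_blur)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_identity_kernel_gradient_direction(self):
        """Zero-length kernel: the λ-term reduces to x − x_blur."""
        op = _identity_op(4)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 4))
        xb = rng.standard_normal((4, 4))
        np.testing.assert_allclose(
            op.apply(op.apply(x) - xb, adjoint=True), x - xb, atol=1e-14
        )

    def test_seeded_run_reproducible(self, schedule):
        rng = np.random.default_rng(2)
        x_blur = rng.standard_normal((5, 5))
        op = _rect_op(0.2, 5)
        den = lambda x, t: 0.05 * x
        cfg = PosteriorConfig(lam=0.4, t_bar=5, seed=42)
        a = deblur_posterior(x_blur, op, den, schedule, cfg)
        b = deblur_posterior(x_blur, op, den, schedule, cfg)
        np.testing.assert_array_equal(a, b)

    def test_invalid_config_rejected(self, schedule):
        with pytest.raises(ValueError):
            PosteriorConfig(lam=-0.1)
        with pytest.raises(ValueError):
            PosteriorConfig(t_bar=0)
        with pytest.raises(ValueError):
            deblur_posterior(
                np.zeros((3, 3)), _identity_op(3), lambda x, t: x, schedule,
                PosteriorConfig(t_bar=schedule.T + 1),
            )


class TestDeblurVolume:
    def test_single_slice_equals_posterior(self, schedule):
        rng = np.random.default_rng(3)
        vol = rng.standard_normal((1, 4, 4))
        op = _rect_op(0.2, 4)
        den = lambda x, t: 0.1 * x
        cfg = PosteriorConfig(lam=0.3, t_bar=4, seed=5)
        out = deblur_volume(vol, [op], den, schedule, cfg)
        single = deblur_posterior(vol[0], op, den, schedule, cfg)
        np.testing.assert_allclose(out[0], single, atol=1e-14)

    def test_slices_processed_independently(self, schedule):
        """Each slice's output equals running the single-slice deblurrer
        with that slice's operator and derived seed; neighbors are
        irrelevant."""
        rng = np.random.default_rng(4)
        vol = rng.standard_normal((3, 4, 4))
        ops = [_rect_op(w, 4) for w in (0.1, 0.2, 0.3)]
        den = lambda x, t: 0.1 * x
        cfg = PosteriorConfig(lam=0.3, t_bar=4, seed=6)
        out = deblur_volume(vol, ops, den, schedule, cfg)
        for k in range(3):
            cfg_k = PosteriorConfig(lam=0.3, t_bar=4, seed=6 + 1000 * k)
            np.testing.assert_allclose(
                out[k],
                deblur_posterior(vol[k], ops[k], den, schedule, cfg_k),
                atol=1e-14,
            )

    def test_operator_count_mismatch(self, schedule):
        with pytest.raises(ValueError):
            deblur_volume(np.zeros((2, 4, 4)), [_identity_op(4)],
                          lambda x, t: x, schedule)


class TestKernelSensitivity:
    def test_true_kernel_beats_halved_kernel(self, lp_scene, trained_prior,
                                             deblurred_slice):
        """Deblurring with the geometry-correct kernel recovers more LP
        contrast than deblurring with a kernel half as long."""
        from dbtblur.metrics import lp_contrast, noise_rms

        denoiser, _ = trained_prior
        half_op = BlurOperator(
            [discretize_kernel(
                0.5 * lp_scene.blur_op.kernels[0].length_mm,
                lp_scene.pixel,
            )],
            lp_scene.x_blur.shape[1],
        )
        out_half = deblur_posterior(
            lp_scene.x_blur, half_op, denoiser,
            cfg=PosteriorConfig(lam=0.4, t_bar=20, seed=11),
        )

        def measure(img):
            cr = lp_contrast(img, lp_scene.spec, lp_scene.pixel,
                             magnification=lp_scene.magnification,
                             bar_amplitude=lp_scene.bar_amplitude)
            return cr.contrast, noise_rms(img, lp_scene.rois).mean

        c_true, n_true = measure(deblurred_slice)
        c_half, n_half = measure(out_half)
        # higher contrast at the resolvable frequencies, comparable noise
        assert c_true[2] > c_half[2]
        assert c_true[3] > c_half[3]
        assert n_true <= 1.1 * n_half


class TestTikhonov:
    def test_identity_blur_returns_input(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((6, 8))
        for mu in (0.0, 0.05, 10.0):
            np.testing.assert_allclose(
                tikhonov_deblur(x, _identity_op(8), mu), x, atol=1e-10
            )

    def test_large_mu_limit_returns_input(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((6, 6))
        out = tikhonov_deblur(x, _rect_op(0.3, 6), mu=1e8)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_matches_dense_circulant_oracle(self):
        """16×16: frequency-domain evaluation equals the dense closed form
        built from the circulant blur matrix."""
        n = 16
        mu = 0.05
        kern = discretize_kernel(0.4, 0.085).samples
        h = kern.size // 2
        B = np.zeros((n, n))
        for i in range(n):
            for o in range(-h, h + 1):
                B[i, (i + o) % n] += kern[o + h]
        rng = np.random.default_rng(7)
        x = rng.standard_normal((n, n))
        dense = np.linalg.solve(B.T @ B + mu * np.eye(n), (B.T + mu * np.eye(n)))
        expected = x @ dense.T
        out = tikhonov_deblur(x, _rect_op(0.4, n), mu=mu)
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_mu_zero_with_spectral_zeros_rejected(self):
        # a two-tap-average kernel has a spectral zero at Nyquist for even n
        op = BlurOperator(
            [BlurKernelSpec(0.0, 0.0, np.array([0.25, 0.5, 0.25]))], 8
        )
        with pytest.raises(ZeroDivisionError):
            tikhonov_deblur(np.zeros((2, 8)), op, mu=0.0)

    def test_contrast_and_noise_increase_as_mu_decreases(self, lp_scene):
        """The inverse filter trades noise for contrast: both rise as μ
        shrinks."""
        from dbtblur.metrics import lp_contrast, noise_rms

        cs, ns = [], []
        for mu in (0.5, 0.05, 0.005):
            out = tikhonov_deblur(lp_scene.x_blur, lp_scene.blur_op, mu=mu)
            cr = lp_contrast(out, lp_scene.spec, lp_scene.pixel,
                             magnification=lp_scene.magnification,
                             bar_amplitude=lp_scene.bar_amplitude)
            cs.append(cr.contrast[-1])  # 2 LP/mm
            ns.append(noise_rms(out, lp_scene.rois).mean)
        assert cs[0] < cs[1] < cs[2]
        assert ns[0] < ns[1] < ns[2]


class TestTV:
    def test_mu_zero_identity_blur_returns_input(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((6, 6))
        out = tv_deblur(x, _identity_op(6), mu_tv=0.0, iters=50)
        np.testing.assert_allclose(out, x, atol=1e-10)

    def test_objective_monotone_non_increasing(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((8, 8))
        _, obj = tv_deblur(x, _rect_op(0.3, 8), mu_tv=0.01, iters=100,
                           return_objective=True)
        assert np.all(np.diff(obj) <= 1e-10 * abs(obj[0]))

    def test_recovers_piecewise_constant_step(self):
        """A step image blurred with a 3-tap kernel is recovered within 5%
        RMSE at small μ_TV."""
        n = 32
        truth = np.zeros((n, n))
        truth[:, n // 2 :] = 1.0
        op = BlurOperator(
            [BlurKernelSpec(0.0, 0.0, np.array([0.25, 0.5, 0.25]))], n
        )
        blurred = op.apply(truth)
        out = tv_deblur(blurred, op, mu_tv=1e-4, iters=500)
        rmse = np.sqrt(np.mean((out - truth) ** 2))
        assert rmse < 0.05 * np.sqrt(np.mean(truth**2))
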