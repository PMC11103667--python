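"""Shared fixtures.

The expensive session fixtures (trained diffusion prior, blurred line-pair
scene) are built once and shared by the end-to-end tests; their
configurations are the package's desk-scale study conditions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from dbtblur.blur import BlurOperator
from dbtblur.deblur import PosteriorConfig, deblur_posterior
from dbtblur.diffusion import TrainConfig, make_schedule, train_denoiser
from dbtblur.geometry import siemens_inspiration
from dbtblur.kernel import discretize_kernel, mean_kernel_length
from dbtblur.metrics import lp_free_roi_centers
from dbtblur.phantoms import LPObjectSpec, make_texture_phantom, render_lp_slice

TEXTURE_BETA = 3.0
TEXTURE_AMPLITUDE = 0.01  # mm^-1, tissue-contrast scale fluctuation
TEXTURE_MEAN = 0.05  # mm^-1, soft-tissue attenuation
SLICE_NOISE_SIGMA = 0.005  # mm^-1, additive slice noise of the blur model


@pytest.fixture(scope="session")
def geom():
    return siemens_inspiration()


@pytest.fixture(scope="session")
def schedule():
    return make_schedule()


@pytest.fixture(scope="session")
def training_fields():
    """Power-law texture realizations emulating clean DBT slices."""
    return np.stack(
        [
            make_texture_phantom(
                (96, 96), TEXTURE_BETA, TEXTURE_AMPLITUDE, seed=s, mean=TEXTURE_MEAN
            )
            for s in range(40)
        ]
    )


@pytest.fixture(scope="session")
def trained_prior(training_fields, schedule):
    """Desk-scale diffusion prior trained on the texture distribution."""
    denoiser, losses = train_denoiser(training_fields, schedule, TrainConfig(seed=7))
    return denoiser, losses


@dataclasses.dataclass
class LPScene:
    """Blurred line-pair slice at z_s = 70 mm with registration metadata."""

    spec: LPObjectSpec
    z_s: float
    magnification: float
    pixel: float
    bar_amplitude: float
    slice_true: np.ndarray
    x_blur: np.ndarray
    blur_op: BlurOperator
    rois: list


@pytest.fixture(scope="session")
def lp_scene(geom):
    spec = LPObjectSpec()
    z_s = 70.0
    mag = geom.magnification(z_s)
    pixel = geom.voxel_xy
    shape = (462, 462)
    background = make_texture_phantom(
        shape, TEXTURE_BETA, TEXTURE_AMPLITUDE, seed=123, mean=TEXTURE_MEAN
    )
    slice_true = render_lp_slice(
        spec,
        pixel,
        shape=shape,
        magnification=mag,
        background=background,
        slice_thickness_mm=geom.voxel_z,
        background_attenuation=TEXTURE_MEAN,
    )
    amp = (spec.bar_attenuation - TEXTURE_MEAN) * spec.thickness / geom.voxel_z
    blur_op = BlurOperator(
        [discretize_kernel(mean_kernel_length(z_s, geom), pixel, z_s)], shape[1]
    )
    rng = np.random.default_rng(321)
    x_blur = blur_op.apply(slice_true) + SLICE_NOISE_SIGMA * rng.standard_normal(shape)
    return LPScene(
        spec=spec,
        z_s=z_s,
        magnification=mag,
        pixel=pixel,
        bar_amplitude=amp,
        slice_true=slice_true,
        x_blur=x_blur,
        blur_op=blur_op,
        rois=lp_free_roi_centers(spec, pixel, shape, magnification=mag),
    )


@pytest.fixture(scope="session")
def deblurred_slice(lp_scene, trained_prior):
    """Posterior-deblurred LP slice at the default λ = 0.4, T̄ = 20."""
    denoiser, _ = trained_prior
    return deblur_posterior(
        lp_scene.x_blur,
        lp_scene.blur_op,
        denoiser,
        cfg=PosteriorConfig(lam=0.4, t_bar=20, seed=11),
    )
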