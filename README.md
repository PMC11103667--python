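# dbtblur

Modeling and removal of x-ray **source-motion blur** in digital breast
tomosynthesis (DBT), for medical-imaging researchers who want a desk-scale,
fully synthetic testbed: no clinical data, no Monte Carlo simulator, one
CPU.

In continuous-motion DBT systems the focal spot travels during each x-ray
pulse.  The effective source becomes a line of length
`w0 = motion_angle·(π/180)·D_SO + nominal_spot` (2.185 mm for the bundled
Siemens Mammomat Inspiration preset), and an impulse at height `z_s` above
the detector acquires a 1D blur along the motion direction.  In the
reconstructed slice the per-angle kernel length is

    w_s(z_s, α) = (w0 / cos α) · z_s / (D_SO·cos α + D_OD),

and the per-slice blur is modeled as a single shift-invariant rect kernel
of the mean length `w̄_s(z_s) = (1/N_p) Σ_α w_s(z_s, α)` — linear in the
slice height, 0.00360 mm/mm for the Siemens geometry.

The package provides:

- **geometry & kernel** — presets and YAML geometries, analytic kernel
  lengths, exact area-sampled discretization, and the per-slice blur
  operator `B` with its adjoint (`dbtblur.geometry`, `.kernel`, `.blur`);
- **forward model** — a sparse ray-driven 2D projector with detector
  aperture integration, plus extended-source simulation via sub-focal
  spots averaged pre-log (the physics) or post-log (the linear `A_sub`
  operator) (`.projector`);
- **verification pipeline** — least-squares reconstruction, impulse OTF
  ratios, sinc fitting, and the kernel-vs-height regression that checks
  the analytic model end to end (`.reconstruct`, `.verify`);
- **deblurring** — diffusion posterior sampling with the data-consistency
  term `−λ·Bᵀ(B x_t − x_blur)` inside DDIM (defaults λ = 0.4, T̄ = 20),
  with Tikhonov and total-variation baselines (`.diffusion`, `.deblur`);
  the noise-predicting network is a small time-conditioned residual CNN
  implemented in numpy with hand-derived backprop (`.nn`);
- **phantoms & metrics** — a line-pair resolution object, power-law
  breast-texture backgrounds, LP contrast, detrended noise RMS, and the
  structural noise-power spectrum with power-law fit (`.phantoms`,
  `.metrics`);
- a `dbtblur` **command line** (`verify-kernel`, `kernel-table`,
  `make-phantom`, `project`, `reconstruct`, `train-prior`, `sample`,
  `deblur`, `evaluate-lp`) that writes CSV/TIFF/HDF5 artifacts plus JSON
  manifests.

See `docs/methods.md` for the model, its assumptions, and every numerical
choice.

## Worked example

Verify the analytic kernel against simulation (impulses at 8 heights,
50 sub-focal spots, least-squares reconstruction, OTF ratio, sinc fit):

```sh
dbtblur verify-kernel --heights 20,30,40,50,60,70,80,90 --out verify.csv
```

prints (about a minute):

```
 z_s    w_hat  w_bar_s   rel_err  fit_residual
20.0 0.068038 0.072054 -0.055743      0.000883
30.0 0.106556 0.108081 -0.014112      0.001615
40.0 0.142964 0.144108 -0.007940      0.001953
50.0 0.182579 0.180135  0.013565      0.001741
60.0 0.217775 0.216162  0.007461      0.002284
70.0 0.254510 0.252190  0.009200      0.002777
80.0 0.295699 0.288217  0.025961      0.004489
90.0 0.331633 0.324244  0.022788      0.004784
zero-intercept slope: 0.00365 mm/mm, correlation: 0.9999
```

`w_hat` is the kernel length recovered from the simulated images, `w_bar_s`
the analytic prediction; the fitted slope sits within 1.5% of the analytic
0.00360 mm/mm and the relation is almost perfectly linear — the
geometric blur model holds at every slice height.

Deblur a synthetic line-pair slice in Python (train the prior once, then
apply it):

```python
import numpy as np
from dbtblur import (siemens_inspiration, mean_kernel_length,
                     discretize_kernel, BlurOperator, LPObjectSpec,
                     render_lp_slice, make_texture_phantom, make_schedule,
                     train_denoiser, TrainConfig, deblur_posterior,
                     PosteriorConfig, lp_contrast, noise_rms,
                     lp_free_roi_centers)

geom = siemens_inspiration()
fields = np.stack([make_texture_phantom((96, 96), 3.0, 0.01, seed=s,
                                        mean=0.05) for s in range(40)])
prior, _ = train_denoiser(fields, make_schedule(), TrainConfig(seed=7))

spec, z = LPObjectSpec(), 70.0
mag = geom.magnification(z)
bg = make_texture_phantom((462, 462), 3.0, 0.01, seed=123, mean=0.05)
truth = render_lp_slice(spec, geom.voxel_xy, shape=(462, 462),
                        magnification=mag, background=bg,
                        background_attenuation=0.05)
B = BlurOperator([discretize_kernel(mean_kernel_length(z, geom),
                                    geom.voxel_xy, z)], 462)
x_blur = B.apply(truth) + 0.005 * np.random.default_rng(321).standard_normal(truth.shape)
x_hat = deblur_posterior(x_blur, B, prior,
                         cfg=PosteriorConfig(lam=0.4, t_bar=20, seed=11))

amp = (spec.bar_attenuation - 0.05) * spec.thickness / geom.voxel_z
rois = lp_free_roi_centers(spec, geom.voxel_xy, truth.shape, magnification=mag)
for name, img in [("blurred", x_blur), ("deblurred", x_hat)]:
    c = lp_contrast(img, spec, geom.voxel_xy, magnification=mag,
                    bar_amplitude=amp).contrast
    n = noise_rms(img, rois).mean
    print(f"{name:10s} contrast(5, 3.3, 2.5, 2 LP/mm) = {np.round(c, 3)}"
          f"  noise = {n:.5f}")
```

```
blurred    contrast(5, 3.3, 2.5, 2 LP/mm) = [-0.171  0.327  0.562  0.681]  noise = 0.00494
deblurred  contrast(5, 3.3, 2.5, 2 LP/mm) = [ 0.018  0.607  0.881  0.923]  noise = 0.00510
```

At 2.5 and 2 LP/mm the contrast rises from 0.56 → 0.88 and 0.68 → 0.92
while the detrended noise changes by about 3% — the posterior sampler
sharpens the bars without amplifying the background noise.  The 5 LP/mm
group sits near the voxel Nyquist frequency (5.88 LP/mm) and is not
recoverable.

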