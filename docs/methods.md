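# Methods

## The physical model

In digital breast tomosynthesis (DBT) the x-ray tube sweeps an arc of
radius `D_SO` about a rotation center located `D_OD` above the detector,
firing one pulse per projection view.  In continuous-motion systems the
focal spot travels during each pulse, so the effective source is a line of
length

    w0 = motion_angle · (π/180) · D_SO + nominal_spot

oriented along the motion tangent (2.185 mm for the bundled
`siemens_inspiration` preset: 0.18° per pulse, 600 mm arm, 0.3 mm nominal
spot).  The spot's extent across the motion (anode–cathode) direction stays
at or below the nominal size and is ignored; the source is treated as a 1D
line.

Projecting an impulse at height `z_s` above the detector through that line
source gives, by triangle similarity, a line-shaped detector PSF of length

    w_d(z_s, α) = (w0 / cos α) · z_s / (D_SO·cos α + D_OD − z_s),

and, referred back to the reconstructed plane at the impulse height,

    w_s(z_s, α) = (w0 / cos α) · z_s / (D_SO·cos α + D_OD).

Both are shift-invariant within a plane at fixed `z_s`.  Across the scan
the per-angle lengths stay within roughly −6.7% / +12.7% (0° / ±25°,
Siemens constants) of their mean

    w̄_s(z_s) = (1/N_p) Σ_α w_s(z_s, α),

so the aggregated blur is modeled as one rect kernel of length `w̄_s(z_s)`
per slice, oriented along the motion direction (the y axis of all image
arrays here).  `w̄_s` is linear in `z_s`; the Siemens slope is
0.00360 mm/mm.  The whole-volume blur operator `B` is block-diagonal:
slice-wise 1D convolution with the height's kernel.

Kernels are discretized by exact rect-cell overlap (area sampling) onto
the reconstruction pitch, giving symmetric, nonnegative, unit-sum taps;
sub-pixel lengths degenerate gracefully to the identity tap.  Convolution
uses mirror (symmetric) boundaries, which preserves constants exactly and
avoids the dark rims zero padding would create; the `wrap` rule is also
available.

## Scan-angle set

The preset uses 25 angles evenly spaced over [−25°, +25°] (spacing
25/12° ≈ 2.0833°).  Equal spacing at exactly 2.08° cannot reach both
printed endpoints, and the evenly spaced set reproduces the −6.7%/+12.7%
per-angle deviation bounds to the printed precision, so the endpoints were
taken as exact.

## Verification by simulation

The kernel derivation is checked end to end on a 2D y–z problem, because
the kernel and every profile of interest are 1D along y:

1. A 0.05 mm⁻¹ impulse (one voxel, 0.085 × 1.0 mm grid) is placed at
   height `z_s`.
2. Projections are simulated for a point source and for the extended
   source.  The extended source is sampled with 50 sub-focal spots at the
   bin centers of a uniform partition of `w0` (angular offsets
   `δ_i = (w0/D_SO)(1/N_sub)(i − (N_sub+1)/2)`); their transmitted
   intensities are averaged before the log, matching the physics (blur
   happens after attenuation).  The simulation is noise-free.
3. Both projection sets are reconstructed with the *point-source* operator
   by unregularized gradient-descent least squares (fixed 200 iterations,
   step 1/L with L from power iteration; neither solver nor iteration
   count is critical because the analysis uses a ratio — see next step).
4. The 1D profile through the impulse along y is extracted from each
   reconstruction; the ratio of their spectra is the source-blur OTF.
   Reconstruction artifacts (limited-angle spokes, solver truncation)
   cancel in the ratio; what remains is real-valued because the source
   blur adds no phase.
5. The ratio is fit with `sinc(w·f)` (the transform of a unit-area rect of
   width `w`) over the band from just above DC to 20% of Nyquist or the
   ratio's first zero crossing, whichever is lower — the ratio is best
   conditioned at low frequency.  The fit uses the real part only; the
   imaginary part is reported as a QA number.
6. Estimates at heights 20–90 mm are regressed through the origin
   (`w = c·z_s`); the slope is compared with the analytic 0.00360 mm/mm
   (3% band) and the linearity via plain Pearson correlation (the
   zero-intercept residual variant would be another defensible choice; the
   plain coefficient is reported).

The projector traces rays slab by slab with exact per-voxel intersection
lengths (a Siddon-type scheme aggregated per z-slab, valid because DBT
rays descend monotonically in z), assembled as a sparse matrix per angle
so the adjoint is the exact transpose.  Each detector cell averages 8
equispaced sub-rays across its aperture; without aperture integration the
point-sampled point-source projection and the aperture-like sub-spot
average are inconsistent at sub-pixel scale and the OTF ratio is badly
biased.  Desk-scale grid: 127 voxels in y, 11 slices around the impulse;
the detector just covers the volume's shadow with margin.

At this scale the pipeline reproduces the slope within ~1.5% with
correlation > 0.999, and moving the impulse ±1.7 mm in y at z_s = 70 mm
changes the estimate by ≲ 1.2% of the mean — the shift-invariance the
model assumes.

## Why not model the blur inside reconstruction

Two modified forward models are provided to demonstrate the negative
result that motivates post-processing deblurring: the blur-composed matrix
`A·B` and the sub-focal-spot matrix `A_sub = (1/N_sub) Σ A(δ_i)` (post-log
averaging — a linear operator, unlike the pre-log physics; they agree to
first order in attenuation and diverge measurably for opaque objects,
which is tested).  Reconstructing blurry projections with either corrects
the negative high-frequency phases the blur imprints on the impulse OTF
but leaves its magnitude far below the point-source condition: the
limited-angle problem is too underdetermined for an unregularized solver
to reinvert the blur.  The test asserts exactly this ordering.

## Diffusion prior and posterior-sampling deblurring

Deblurring treats each reconstructed slice as `x_blur = B·x_true + n`,
with `B` known from geometry, and samples the posterior by steering a
denoising-diffusion chain.  The forward process uses the standard linear
variance schedule (β from 1e-4 to 0.02, T = 1000); a noise-predicting
network ε_θ(x_t, t) is trained with the usual MSE objective over uniform
steps and Gaussian noise.  Sampling is deterministic DDIM; the score
relation `∇log p = −ε_θ/√(1−ᾱ_t)` links the predictor to the posterior
gradient, and the data-consistency term enters the update as
`−λ·Bᵀ(B x_t − x_blur)` with a single t-independent weight λ (the noise
variance of the blur model is absorbed into λ).  Defaults λ = 0.4 and
T̄ = 20 steps; the chain starts from the blurry slice forward-diffused to
step T̄ with seeded noise, which makes λ = 0 a pure unconditional
refinement of the input and respects the small-t approximation behind the
data term.  Volumes are deblurred slice by slice, each slice with its own
kernel and a seed derived from the base seed and slice index.

ε_θ is a compact time-conditioned residual CNN written directly in numpy
(hand-derived backprop, Adam, float32): input conv to 16 channels, three
residual blocks (each conditioned by a per-channel bias from a sinusoidal
step embedding), zero-initialized output conv.  It is fully convolutional
— no attention, no resampling — so one trained model applies to any slice
size.  Optional per-block dilations are supported but the default is
plain 3×3 stacks: the small-t denoising that dominates deblurring is a
local high-pass problem and dilation measurably hurt it.  Desk-scale
training: 32×32 patches from 40 texture fields of 96², batch 16,
learning rate 1e-4, 5000 Adam steps (about 13 minutes on one CPU).  A
larger full-scale configuration (more blocks/channels, 64×64 patches)
is reachable through the same `TrainConfig`, at proportional cost.
Training intensities are mapped to [−1, 1] by the dataset-global min/max,
stored with the checkpoint; a constant dataset falls back to a unit band.
Gradients are verified against finite differences in the test suite.

Baselines: Tikhonov deblurring uses the printed closed form
`(BᵀB + μI)⁻¹(Bᵀ + μI)·x_blur` (μ = 0.05) evaluated in the frequency
domain, which treats the kernel as circulant along y — the dense oracle in
the tests uses the same circulant matrix, while the posterior and TV
methods use the mirror-boundary operator.  TV deblurring minimizes
`½‖Bv − x_blur‖² + μ_TV‖Dv‖₁` (anisotropic forward differences,
μ_TV = 0.0005) by gradient descent on a Charbonnier-smoothed TV
(ε = 1e-6) with backtracking; this guarantees the monotone objective
decrease that the tests assert, which proximal-style splittings do not.

## Synthetic study conditions

No clinical or Monte Carlo data are used.  Clean slices are emulated by
stationary Gaussian random fields with power-law structural spectrum
(power ∝ f^−β, β = 3, the regime reported for breast backgrounds), mean
0.05 mm⁻¹ (soft tissue) and standard deviation 0.01 mm⁻¹ (tissue-contrast
scale).  The line-pair (LP) test object is four frequency groups (5, 3.33,
2.5, 2 LP/mm) of five bars each, duplicated in five columns with a
cumulative 0.05 mm shift to average over voxel-grid alignment; bars are
0.2 mm thick and use a configurable attenuation (default 0.5 mm⁻¹ — no
monoenergetic coefficient for the calcium oxalate of physical inserts is
available, so the bar signal in a rendered slice is the thickness-weighted
excess over background).  Rendered layouts are scaled by the slice's
cone-beam magnification (1.12 at z_s = 70 mm).

The degraded input of the end-to-end study is `B·x_true + n` with additive
Gaussian slice noise σ = 0.005 mm⁻¹ (half the texture amplitude).  The
noise term is part of the degradation model the method is built for:
reconstructed low-dose DBT slices are noisy, and the diffusion prior's
role is precisely to keep that noise from being amplified by the
deconvolution.  A noise-free input would make the detrended "noise" metric
measure texture roughness, which deblurring legitimately restores — the
wrong quantity.

What these synthetics do not emulate: scatter, detector blur and
correlated noise, dose/AEC effects, anatomical structure beyond
second-order statistics, and the inter-plane artifacts of full
reconstructions.  Passing tests show the method's mechanics — kernel
correctness, posterior-sampling behavior, contrast/noise trade-off — not
clinical performance.

## Metrics

LP contrast: the central 1.5 mm of each bar group is averaged along x, the
y-profile is linearly interpolated, and the mean over the five true bar
intervals minus the mean over the four space intervals is normalized by
the same statistic of the ideal binary profile (so an ideal rendering
scores 1, a constant image 0, and the measure is invariant to affine
intensity maps when the stated bar amplitude is scaled accordingly).  The
contrast per frequency is the mean over the five shifted columns.

Noise: root-mean-square residual of 10×10 ROIs after removing a
6-coefficient quadratic surface, averaged over a deterministic grid of 20
LP-free ROIs in the gaps between columns; for white noise the expected
value is √(94/100)·σ from the residual degrees of freedom, which the tests
verify by Monte Carlo.

Structural NPS: mean-subtracted, Hann-windowed (variance-corrected)
periodograms averaged over realizations and radially binned; the power-law
exponent comes from a log–log fit over all nonzero-frequency bins up to
the axis Nyquist.  The estimator recovers β within 0.3 at 256² with 10
realizations, and β from samples of the trained prior is compared with the
training textures' within a deliberately loose band of 1.0 — a
stochastic check that the prior learned the texture's second-order
statistics.

## Numerical choices and degenerate inputs

- OTF ratio: frequencies where the point spectrum falls below 5% of its
  maximum are masked out of the fit rather than propagated.
- Sinc fit: normalized sinc, nonnegative-width bound, second-moment
  initial guess; at least 3 retained samples required.
- Power iteration: 50 iterations, fixed seed; gradient descent raises if
  the objective increases beyond round-off.
- Degenerate kernels (length below ~1e-12 of a pixel) are the identity
  tap; kernel discretization enforces exact symmetry against accumulated
  floating-point drift.
- Tikhonov with μ = 0 demands a zero-free kernel spectrum and raises
  otherwise.
- The λ-term with an identity kernel reduces to `x − x_blur` exactly.

## Problem sizes

Chosen once for desk-scale reproducibility on a single CPU: verification
grid 127 × 11 voxels with 8 heights and 3 in-plane shifts (about a minute);
limitation study at z_s = 70 mm (under a minute); prior training 5000
steps (~13 min); end-to-end deblurring on a 462² slice containing the full
LP object (tens of seconds per λ); λ-grid monotonicity on a 140-row band
of the same slice.

## Known limitations

- The projector is 2D (y–z); the thin 3D path for LP imaging renders the
  object directly into slices rather than projecting a 3D volume.
- The desk-scale prior is far smaller than a production U-Net; its
  residual small-t denoising error is the main gap between the ideal and
  achieved noise level after deblurring.
- Tikhonov's circulant boundary differs from the mirror boundary of the
  other operators near slice edges.
- The LP bar attenuation is a configurable stand-in, not a spectrum-derived
  coefficient.
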