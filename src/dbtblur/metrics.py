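"""Image-quality metrics: line-pair contrast, detrended noise, structural NPS.

LP contrast follows the bar/space convention of physical resolution
phantoms: the y-profile through a bar group (averaged over the central bar
length along x) is compared between the ground-truth bar and space
intervals, and normalized by the same statistic of the ideal binary
profile, so a perfectly rendered object scores 1 and a constant image 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .phantoms import LPObjectSpec, bar_intervals, render_lp_slice, space_intervals

__all__ = [
    "ContrastResult",
    "NoiseResult",
    "NPSResult",
    "lp_contrast",
    "noise_rms",
    "lp_free_roi_centers",
    "structural_nps",
]


@dataclasses.dataclass
class ContrastResult:
    frequencies: np.ndarray  # LP/mm
    contrast: np.ndarray  # per frequency, mean over shifted columns
    per_instance: np.ndarray  # (n_freq, n_columns)


@dataclasses.dataclass
class NoiseResult:
    per_roi: np.ndarray
    mean: float


@dataclasses.dataclass
class NPSResult:
    freqs: np.ndarray  # cycles/mm (radial)
    power: np.ndarray
    exponent: float  # β of power ∝ f^−β
    log_amplitude: float


def _interval_mean(profile_y: np.ndarray, pixel: float, lo: float, hi: float,
                   n_samp: int = 64) -> float:
    """Mean of the linearly interpolated profile over [lo, hi] (mm).

    ``profile_y[j]`` sits at the pixel center ``(j + 1/2)·pixel``.
    """
    centers = (np.arange(profile_y.size) + 0.5) * pixel
    ys = np.linspace(lo, hi, n_samp)
    return float(np.mean(np.interp(ys, centers, profile_y)))


def _instance_contrast(
    image: np.ndarray,
    spec: LPObjectSpec,
    pixel: float,
    group: int,
    column: int,
    mag: float,
    x_window: float,
) -> float:
    x_lo, x_hi = spec.column_x(column)
    xc = 0.5 * (x_lo + x_hi) * mag
    centers_x = (np.arange(image.shape[0]) + 0.5) * pixel
    cols = np.where(np.abs(centers_x - xc) <= x_window / 2.0)[0]
    if cols.size == 0:
        raise ValueError("LP layout lies outside the image along x")
    profile = image[cols].mean(axis=0)
    bars = [
        _interval_mean(profile, pixel, lo * mag, hi * mag)
        for lo, hi in bar_intervals(spec, group, column)
    ]
    spaces = [
        _interval_mean(profile, pixel, lo * mag, hi * mag)
        for lo, hi in space_intervals(spec, group, column)
    ]
    return float(np.mean(bars) - np.mean(spaces))


def lp_contrast(
    image: np.ndarray,
    spec: LPObjectSpec,
    pixel_mm: float,
    magnification: float = 1.0,
    bar_amplitude: float = 1.0,
    x_window_mm: float = 1.5,
) -> ContrastResult:
    """Normalized LP contrast of a reconstructed/processed slice.

    ``bar_amplitude`` is the bar signal in the image's intensity units (the
    thickness-weighted attenuation excess for a rendered slice); the raw
    bar-minus-space difference is normalized by the same difference of the
    ideal binary profile rendered with that amplitude, making the result
    unitless with ideal value 1.  Contrast per frequency is the mean over
    the shifted columns.
    """
    image = np.asarray(image, float)
    n_f, n_c = len(spec.bar_widths), spec.n_columns
    ideal = render_lp_slice(
        spec,
        pixel_mm,
        shape=image.shape,
        magnification=magnification,
        slice_thickness_mm=spec.thickness,  # unit thickness weighting
    ) / spec.bar_attenuation * bar_amplitude
    raw = np.empty((n_f, n_c))
    norm = np.empty((n_f, n_c))
    for g in range(n_f):
        for c in range(n_c):
            raw[g, c] = _instance_contrast(
                image, spec, pixel_mm, g, c, magnification, x_window_mm
            )
            norm[g, c] = _instance_contrast(
                ideal, spec, pixel_mm, g, c, magnification, x_window_mm
            )
    per_instance = raw / norm
    return ContrastResult(
        frequencies=spec.frequencies,
        contrast=per_instance.mean(axis=1),
        per_instance=per_instance,
    )


# ---------------------------------------------------------------------------
# noise


def _quadratic_design(n: int) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    i = (ii.ravel() - (n - 1) / 2.0) / n
    j = (jj.ravel() - (n - 1) / 2.0) / n
    return np.column_stack([np.ones_like(i), i, j, i * i, i * j, j * j])


def noise_rms(
    image: np.ndarray,
    roi_centers: list[tuple[int, int]],
    roi_size: int = 10,
) -> NoiseResult:
    """RMS pixel variation after quadratic background removal, per ROI.

    Each ``roi_size²`` ROI is fit with a 6-coefficient 2D quadratic
    surface; the RMS of the residual (normalized by the pixel count) is
    averaged over ROIs.  Exactly quadratic surfaces give zero.
    """
    image = np.asarray(image, float)
    design = _quadratic_design(roi_size)
    h = roi_size // 2
    vals = []
    for ci, cj in roi_centers:
        i0, j0 = ci - h, cj - h
        if i0 < 0 or j0 < 0 or i0 + roi_size > image.shape[0] or j0 + roi_size > image.shape[1]:
            raise ValueError(f"ROI at {(ci, cj)} out of bounds")
        roi = image[i0 : i0 + roi_size, j0 : j0 + roi_size].ravel()
        coef, *_ = np.linalg.lstsq(design, roi, rcond=None)
        res = roi - design @ coef
        vals.append(np.sqrt(np.mean(res**2)))
    vals = np.asarray(vals)
    return NoiseResult(per_roi=vals, mean=float(vals.mean()))


def lp_free_roi_centers(
    spec: LPObjectSpec,
    pixel_mm: float,
    shape: tuple[int, int],
    magnification: float = 1.0,
    n_rois: int = 20,
) -> list[tuple[int, int]]:
    """Deterministic LP-free ROI grid in the gaps between bar columns.

    Places ROIs at the x-midpoints between adjacent columns (and after the
    last), vertically aligned with each frequency group, clipped to the
    image; yields ``n_rois`` centers.
    """
    xs = []
    for c in range(spec.n_columns):
        x_lo, x_hi = spec.column_x(c)
        xs.append(x_hi + (spec.column_pitch - spec.bar_length) / 2.0)
    ys = []
    for g in range(len(spec.bar_widths)):
        ivs = bar_intervals(spec, g, 0)
        ys.append(0.5 * (ivs[0][0] + ivs[-1][1]))
    centers = []
    for y in ys:
        for x in xs:
            i = int(round(x * magnification / pixel_mm))
            j = int(round(y * magnification / pixel_mm))
            i = int(np.clip(i, 6, shape[0] - 7))
            j = int(np.clip(j, 6, shape[1] - 7))
            centers.append((i, j))
    return centers[:n_rois]


# ---------------------------------------------------------------------------
# structural NPS


def structural_nps(
    images,
    pixel_mm: float = 1.0,
    window: str = "hann",
) -> NPSResult:
    """Radially averaged structural noise power spectrum with power-law fit.

    Each image is mean-subtracted, tapered with a variance-corrected Hann
    window, and periodogrammed; the periodograms are averaged over images,
    radially binned, and fit with ``log P = log A − β·log f`` over all
    nonzero-frequency bins up to the axis Nyquist.
    """
    arrs = [np.asarray(a, float) for a in images]
    if not arrs:
        raise ValueError("need at least one image")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all images must share a common shape")
    if min(shape) < 2:
        raise ValueError("images must have at least 2 pixels per axis")
    if window == "hann":
        w = np.outer(np.hanning(shape[0]), np.hanning(shape[1]))
        w = w / np.sqrt(np.mean(w**2))
    elif window is None or window == "none":
        w = np.ones(shape)
    else:
        raise ValueError(f"unknown window {window!r}")
    n_pix = shape[0] * shape[1]
    acc = np.zeros(shape)
    for a in arrs:
        d = (a - a.mean()) * w
        acc += np.abs(np.fft.fft2(d)) ** 2
    psd = acc / (len(arrs) * n_pix) * pixel_mm**2
    fy = np.fft.fftfreq(shape[0], d=pixel_mm)[:, None]
    fx = np.fft.fftfreq(shape[1], d=pixel_mm)[None, :]
    fr = np.hypot(fy, fx).ravel()
    p = psd.ravel()
    nyq = 0.5 / pixel_mm
    df = 1.0 / (min(shape) * pixel_mm)
    nbins = int(np.floor(nyq / df))
    idx = np.floor(fr / df).astype(int)
    keep = (idx >= 1) & (idx <= nbins) & (fr <= nyq)
    counts = np.bincount(idx[keep], minlength=nbins + 1)
    sums = np.bincount(idx[keep], weights=p[keep], minlength=nbins + 1)
    valid = counts > 0
    valid[0] = False
    freqs = (np.arange(nbins + 1) + 0.5) * df
    power = np.full(nbins + 1, np.nan)
    power[valid] = sums[valid] / counts[valid]
    fsel = freqs[valid]
    psel = power[valid]
    pos = psel > 0
    coef = np.polyfit(np.log(fsel[pos]), np.log(psel[pos]), 1)
    return NPSResult(
        freqs=fsel,
        power=psel,
        exponent=float(-coef[0]),
        log_amplitude=float(coef[1]),
    )
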