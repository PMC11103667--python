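"""Analytic source-motion blur kernel for reconstructed DBT slices.

For a continuously moving x-ray source the focal spot is effectively
elongated along the motion tangent.  Projected through the system geometry,
an impulse at height ``z_s`` above the detector acquires a 1D line blur along
the motion direction.  The kernel length at the detector follows from
triangle similarity,

    w_d(z_s, α) = (w0/cosα) · z_s / (D_SO·cosα + D_OD − z_s),

and back in the reconstructed slice at the impulse height,

    w_s(z_s, α) = (w0/cosα) · z_s / (D_SO·cosα + D_OD).

Across scan angles the per-angle lengths stay close to their mean
``w̄_s(z_s)``, so the aggregated in-plane blur is modeled as a single
shift-invariant line kernel of that mean length, one kernel per slice
height.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DBTGeometry

__all__ = [
    "effective_source_length",
    "detector_psf_length",
    "inplane_psf_length",
    "mean_kernel_length",
    "magnification",
    "discretize_kernel",
    "BlurKernelSpec",
    "kernel_table",
]


def effective_source_length(
    motion_angle_deg: float, D_SO: float, nominal_mm: float
) -> float:
    """Effective focal spot length w0 along the motion tangent, mm.

    The nominal spot is elongated by the arc length traveled during the
    pulse: ``w0 = motion_angle·(π/180)·D_SO + nominal``.
    """
    if motion_angle_deg < 0 or D_SO < 0 or nominal_mm < 0:
        raise ValueError("effective_source_length arguments must be >= 0")
    return math.radians(motion_angle_deg) * D_SO + nominal_mm


def _w0(geom: DBTGeometry) -> float:
    return effective_source_length(
        geom.motion_angle_per_pulse, geom.D_SO, geom.nominal_focal_spot
    )


def _check_height(z_s: float, geom: DBTGeometry, alpha_deg: float) -> float:
    sdd = geom.D_SO * math.cos(math.radians(alpha_deg)) + geom.D_OD
    if not 0 <= z_s < sdd:
        raise ValueError(
            f"slice height z_s={z_s} must lie in [0, {sdd}) at alpha={alpha_deg}"
        )
    return sdd


def detector_psf_length(z_s: float, alpha_deg: float, geom: DBTGeometry) -> float:
    """Length w_d of the impulse PSF projected onto the detector, mm."""
    sdd = _check_height(z_s, geom, alpha_deg)
    ca = math.cos(math.radians(alpha_deg))
    return (_w0(geom) / ca) * z_s / (sdd - z_s)


def inplane_psf_length(z_s: float, alpha_deg: float, geom: DBTGeometry) -> float:
    """Length w_s of the in-plane PSF in the reconstructed slice, mm."""
    sdd = _check_height(z_s, geom, alpha_deg)
    ca = math.cos(math.radians(alpha_deg))
    return (_w0(geom) / ca) * z_s / sdd


def mean_kernel_length(z_s: float, geom: DBTGeometry) -> float:
    """Mean in-plane kernel length w̄_s(z_s) averaged over all scan angles, mm.

    Linear in ``z_s``; the slope is the geometry's blur-per-height constant
    (0.00360 mm/mm for the Siemens preset).
    """
    return float(
        np.mean([inplane_psf_length(z_s, a, geom) for a in geom.scan_angles])
    )


def magnification(z_s: float, geom: DBTGeometry) -> float:
    """Central-view magnification of the slice at height ``z_s``."""
    return geom.magnification(z_s)


@dataclasses.dataclass(frozen=True)
class BlurKernelSpec:
    """Discretized 1D blur kernel for one slice height.

    ``samples`` are nonnegative, symmetric about the central tap, and sum to
    one; they are the exact overlaps of a centered rectangle of width
    ``length_mm`` with detector-pitch cells.
    """

    length_mm: float
    z_s: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if self.length_mm < 0:
            raise ValueError("length_mm must be >= 0")
        if s.ndim != 1 or s.size % 2 != 1:
            raise ValueError("samples must be a 1D odd-length array")
        if np.any(s < 0):
            raise ValueError("samples must be nonnegative")
        if abs(s.sum() - 1.0) > 1e-12:
            raise ValueError("samples must sum to 1")
        if not np.allclose(s, s[::-1], rtol=0, atol=1e-14):
            raise ValueError("samples must be symmetric about the center")
        object.__setattr__(self, "samples", s)


def discretize_kernel(
    length_mm: float, pixel_mm: float, z_s: float = 0.0
) -> BlurKernelSpec:
    """Area-sample a centered rectangle of width ``length_mm`` onto pixels.

    Tap ``j`` covers the cell ``[(j−1/2)·p, (j+1/2)·p]``; its weight is the
    fraction of the rectangle overlapping that cell.  Lengths below one pixel
    give near-delta taps; length zero gives the identity kernel ``[1]``.
    """
    if length_mm < 0:
        raise ValueError("length_mm must be >= 0")
    if pixel_mm <= 0:
        raise ValueError("pixel_mm must be positive")
    if length_mm <= 1e-12 * pixel_mm:
        return BlurKernelSpec(float(length_mm), z_s, np.array([1.0]))
    half = 0.5 * length_mm
    jmax = int(math.floor((half + 0.5 * pixel_mm) / pixel_mm - 1e-12))
    j = np.arange(-jmax, jmax + 1)
    lo = np.maximum((j - 0.5) * pixel_mm, -half)
    hi = np.minimum((j + 0.5) * pixel_mm, half)
    w = np.clip(hi - lo, 0.0, None)
    w /= w.sum()
    # enforce exact symmetry against floating-point drift
    w = 0.5 * (w + w[::-1])
    w /= w.sum()
    return BlurKernelSpec(float(length_mm), float(z_s), w)


def kernel_table(
    heights_mm, geom: DBTGeometry, pixel_mm: float | None = None
) -> pd.DataFrame:
    """Tabulate the mean kernel length and its taps at the given heights.

    Returns a frame with columns ``z_s``, ``w_bar_s`` and ``taps`` (the
    discretized weights as a comma-joined string, exportable as CSV).
    """
    pixel = geom.voxel_xy if pixel_mm is None else pixel_mm
    rows = []
    for z in heights_mm:
        w = mean_kernel_length(z, geom)
        spec = discretize_kernel(w, pixel, z_s=z)
        rows.append(
            {
                "z_s": float(z),
                "w_bar_s": w,
                "taps": ",".join(f"{v:.8g}" for v in spec.samples),
            }
        )
    return pd.DataFrame(rows)


def export_kernel_table(path: str | Path, heights_mm, geom: DBTGeometry) -> None:
    kernel_table(heights_mm, geom).to_csv(path, index=False)
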