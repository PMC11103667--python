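"""Test objects and synthetic backgrounds.

Two generators live here: a line-pair (LP) resolution test object with bar
groups at 5, 3.33, 2.5 and 2 line pairs per mm, and a stationary Gaussian
random field with a power-law structural noise power spectrum
(power ∝ f^−β) emulating the statistical texture of reconstructed breast
tissue slices.  The LP object mirrors the common physical resolution
phantoms: four frequency groups of five bars each, duplicated in five
columns with a cumulative sub-pixel vertical shift so that measurements
average over the possible alignments of the bars with the voxel grid.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "LPObjectSpec",
    "bar_intervals",
    "space_intervals",
    "make_lp_object",
    "render_lp_slice",
    "make_texture_phantom",
]


@dataclasses.dataclass(frozen=True)
class LPObjectSpec:
    """Geometry of the line-pair test object (dimensions in mm).

    Bars run along x (length ``bar_length``); their width and spacing along
    y set the spatial frequency ``1/(2·width)``.  Frequency groups are
    stacked along y with pitch ``group_pitch``; shifted duplicate columns
    are placed along x with pitch ``column_pitch``, column k shifted down
    by ``k·column_shift``.
    """

    bar_widths: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25)
    bars_per_group: int = 5
    bar_length: float = 2.0
    thickness: float = 0.2
    extent: float = 35.0
    fine_voxel: float = 0.05
    n_columns: int = 5
    column_shift: float = 0.05
    group_pitch: float = 10.0
    column_pitch: float = 7.0
    bar_attenuation: float = 0.5
    margin: float = 2.0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.bar_widths):
            raise ValueError("bar widths must be positive")
        if self.bars_per_group < 1 or self.n_columns < 1:
            raise ValueError("need at least one bar and one column")
        max_block = (2 * self.bars_per_group - 1) * max(self.bar_widths)
        y_need = (
            self.margin
            + (len(self.bar_widths) - 1) * self.group_pitch
            + max_block
            + (self.n_columns - 1) * self.column_shift
        )
        x_need = self.margin + (self.n_columns - 1) * self.column_pitch + self.bar_length
        if y_need > self.extent or x_need > self.extent:
            raise ValueError("LP layout does not fit within the object extent")

    @property
    def frequencies(self) -> np.ndarray:
        """Spatial frequency of each group, line pairs per mm."""
        return 1.0 / (2.0 * np.asarray(self.bar_widths))

    def column_x(self, column: int) -> tuple[float, float]:
        """x-interval covered by the bars of one column."""
        x0 = self.margin + column * self.column_pitch
        return (x0, x0 + self.bar_length)


def bar_intervals(spec: LPObjectSpec, group: int, column: int) -> list[tuple[float, float]]:
    """y-intervals of the bars of one LP instance (object coordinates)."""
    w = spec.bar_widths[group]
    base = spec.margin + group * spec.group_pitch + column * spec.column_shift
    return [
        (base + 2 * i * w, base + (2 * i + 1) * w) for i in range(spec.bars_per_group)
    ]


def space_intervals(spec: LPObjectSpec, group: int, column: int) -> list[tuple[float, float]]:
    """y-intervals of the spaces between the bars of one LP instance."""
    w = spec.bar_widths[group]
    base = spec.margin + group * spec.group_pitch + column * spec.column_shift
    return [
        (base + (2 * i + 1) * w, base + (2 * i + 2) * w)
        for i in range(spec.bars_per_group - 1)
    ]


def _render(spec: LPObjectSpec, pixel: float, shape: tuple[int, int],
            scale: float, amplitude: float) -> np.ndarray:
    """Area-sampled rendering of the (possibly magnified) bar layout.

    Pixel (i, j) covers ``[i·p, (i+1)·p] × [j·p, (j+1)·p]`` in (x, y); each
    bar contributes its exact area overlap fraction times ``amplitude``.
    """
    n_x, n_y = shape
    img = np.zeros(shape)
    xe = np.arange(n_x + 1) * pixel
    ye = np.arange(n_y + 1) * pixel
    for g in range(len(spec.bar_widths)):
        for c in range(spec.n_columns):
            x_lo, x_hi = (v * scale for v in spec.column_x(c))
            ix0 = max(int(np.floor(x_lo / pixel)), 0)
            ix1 = min(int(np.ceil(x_hi / pixel)), n_x)
            if ix1 <= ix0:
                continue
            fx = (
                np.clip(np.minimum(xe[ix0 + 1 : ix1 + 1], x_hi)
                        - np.maximum(xe[ix0:ix1], x_lo), 0.0, None)
                / pixel
            )
            for y_lo, y_hi in bar_intervals(spec, g, c):
                y_lo, y_hi = y_lo * scale, y_hi * scale
                iy0 = max(int(np.floor(y_lo / pixel)), 0)
                iy1 = min(int(np.ceil(y_hi / pixel)), n_y)
                if iy1 <= iy0:
                    continue
                fy = (
                    np.clip(np.minimum(ye[iy0 + 1 : iy1 + 1], y_hi)
                            - np.maximum(ye[iy0:iy1], y_lo), 0.0, None)
                    / pixel
                )
                img[ix0:ix1, iy0:iy1] += amplitude * fx[:, None] * fy[None, :]
    return img


def make_lp_object(spec: LPObjectSpec = LPObjectSpec()) -> np.ndarray:
    """Voxelize the LP object on its fine grid (attenuation map, mm⁻¹).

    Returns a 2D (x, y) array at ``spec.fine_voxel`` pitch; the 0.2 mm
    physical thickness is carried by the spec and applied when the object
    is embedded into a thicker slice.
    """
    n = int(round(spec.extent / spec.fine_voxel))
    return _render(spec, spec.fine_voxel, (n, n), 1.0, spec.bar_attenuation)


def render_lp_slice(
    spec: LPObjectSpec,
    pixel_mm: float,
    shape: tuple[int, int] | None = None,
    magnification: float = 1.0,
    background: np.ndarray | float = 0.0,
    slice_thickness_mm: float = 1.0,
    background_attenuation: float = 0.0,
) -> np.ndarray:
    """Render the LP object into a reconstructed-slice image.

    The layout is scaled by ``magnification`` (the cone-beam magnification
    of the slice height) and area-sampled at the reconstruction pitch.  The
    bar signal is the thickness-weighted attenuation excess over the
    background averaged over the slice thickness:
    ``(bar_att − bg_att)·(thickness/slice_thickness)``.
    """
    if shape is None:
        n = int(np.ceil(spec.extent * magnification / pixel_mm))
        shape = (n, n)
    amp = (spec.bar_attenuation - background_attenuation) * (
        spec.thickness / slice_thickness_mm
    )
    img = _render(spec, pixel_mm, shape, magnification, amp)
    return img + background


def make_texture_phantom(
    shape: tuple[int, int],
    beta: float = 3.0,
    amplitude: float = 0.01,
    seed: int | np.random.Generator = 0,
    mean: float = 0.05,
) -> np.ndarray:
    """Stationary Gaussian random field with power-law spectrum.

    The amplitude spectrum is ∝ f^(−beta/2), i.e. noise power ∝ f^−beta —
    the structural spectrum reported for mammographic backgrounds (β ≈ 3).
    ``amplitude`` sets the standard deviation of the field and ``mean`` its
    zero-frequency (DC) level.  β = 0 gives white noise.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n0, n1 = shape
    fy = np.fft.fftfreq(n0)[:, None]
    fx = np.fft.fftfreq(n1)[None, :]
    f = np.hypot(fy, fx)
    filt = np.zeros(f.shape)
    nz = f > 0
    filt[nz] = f[nz] ** (-beta / 2.0)
    spec = np.fft.fft2(rng.standard_normal(shape)) * filt
    field = np.fft.ifft2(spec).real
    sd = field.std()
    if sd > 0:
        field *= amplitude / sd
    return field + mean
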