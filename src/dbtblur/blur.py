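"""Per-slice shift-invariant blur operator B.

The source-motion blur of a reconstructed DBT volume is block-diagonal over
slices: each slice is convolved along the source-motion direction (the last
array axis, y) with the 1D kernel for its height.  The operator is linear,
exposes its exact adjoint, and can materialize the dense per-slice matrix
for small problems (used by the test oracles).

Boundary handling is symmetric (mirror) reflection by default, which keeps
each matrix row summing to one, so constant images are preserved exactly.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import scipy.sparse as sp

from .geometry import DBTGeometry
from .kernel import BlurKernelSpec, discretize_kernel, mean_kernel_length

__all__ = ["BlurOperator", "apply_blur"]


def _reflect_indices(idx: np.ndarray, n: int, boundary: str) -> np.ndarray:
    if boundary == "symmetric":
        m = np.mod(idx, 2 * n)
        return np.where(m >= n, 2 * n - 1 - m, m)
    if boundary == "wrap":
        return np.mod(idx, n)
    raise ValueError(f"unknown boundary rule {boundary!r}")


class BlurOperator:
    """Blur operator over one or more slices.

    Parameters
    ----------
    kernels : sequence of BlurKernelSpec
        One kernel per slice.  A single kernel makes the operator applicable
        to any array, blurring along the last axis; with several kernels the
        leading axis of the input must index slices.
    n_y : int
        Number of samples along the blur (y) axis.
    boundary : {"symmetric", "wrap"}
        Edge rule for the convolution.
    """

    def __init__(
        self,
        kernels: Sequence[BlurKernelSpec],
        n_y: int,
        boundary: str = "symmetric",
    ) -> None:
        if len(kernels) == 0:
            raise ValueError("need at least one kernel")
        if n_y < 1:
            raise ValueError("n_y must be positive")
        self.kernels = list(kernels)
        self.n_y = int(n_y)
        self.boundary = boundary
        self._matrices: dict[int, sp.csr_matrix] = {}

    @classmethod
    def from_geometry(
        cls,
        geom: DBTGeometry,
        slice_heights_mm: Sequence[float],
        n_y: int,
        pixel_mm: float | None = None,
        boundary: str = "symmetric",
    ) -> "BlurOperator":
        """Build the operator from the analytic mean kernel at each height."""
        pixel = geom.voxel_xy if pixel_mm is None else pixel_mm
        kernels = [
            discretize_kernel(mean_kernel_length(z, geom), pixel, z_s=z)
            for z in slice_heights_mm
        ]
        return cls(kernels, n_y, boundary=boundary)

    @property
    def n_slices(self) -> int:
        return len(self.kernels)

    def matrix(self, slice_index: int = 0) -> sp.csr_matrix:
        """The dense-equivalent (n_y × n_y) convolution matrix of one slice."""
        if slice_index not in self._matrices:
            k = self.kernels[slice_index].samples
            h = k.size // 2
            n = self.n_y
            rows, cols, vals = [], [], []
            i = np.arange(n)
            for o in range(-h, h + 1):
                rows.append(i)
                cols.append(_reflect_indices(i + o, n, self.boundary))
                vals.append(np.full(n, k[o + h]))
            m = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(n, n),
            ).tocsr()
            self._matrices[slice_index] = m
        return self._matrices[slice_index]

    def _apply_slice(self, arr: np.ndarray, idx: int, adjoint: bool) -> np.ndarray:
        m = self.matrix(idx)
        flat = arr.reshape(-1, self.n_y)
        out = np.asarray(flat @ m if adjoint else flat @ m.T)
        return out.reshape(arr.shape)

    def apply(self, arr: np.ndarray, adjoint: bool = False) -> np.ndarray:
        """Apply B (or Bᵀ) to a slice image or a volume.

        With one kernel, any array shaped ``(..., n_y)`` is accepted.  With
        several kernels, the array must be ``(n_slices, ..., n_y)`` and each
        slice gets its own kernel.
        """
        arr = np.asarray(arr, dtype=float)
        if arr.shape[-1] != self.n_y:
            raise ValueError(
                f"last axis has {arr.shape[-1]} samples, operator expects {self.n_y}"
            )
        if self.n_slices == 1:
            return self._apply_slice(arr, 0, adjoint)
        if arr.shape[0] != self.n_slices:
            raise ValueError(
                f"leading axis has {arr.shape[0]} slices, operator has {self.n_slices}"
            )
        return np.stack(
            [self._apply_slice(arr[i], i, adjoint) for i in range(self.n_slices)]
        )

    def __call__(self, arr: np.ndarray) -> np.ndarray:
        return self.apply(arr)


def apply_blur(
    arr: np.ndarray, operator: BlurOperator, adjoint: bool = False
) -> np.ndarray:
    """Functional form of :meth:`BlurOperator.apply`."""
    return operator.apply(arr, adjoint=adjoint)
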