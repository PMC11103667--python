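"""Unregularized least-squares DBT reconstruction by gradient descent.

The reconstruction solves ``argmin_v ½‖Op v − y‖²`` for a pluggable linear
forward operator: the point-source matrix A, the blur-composed matrix AB, or
the sub-focal-spot matrix A_sub.  The step size defaults to 1/L with the
Lipschitz constant L = ‖OpᵀOp‖ estimated by power iteration, which makes the
objective non-increasing.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .blur import BlurOperator

__all__ = ["MatrixOperator", "ABOperator", "power_iteration", "lsq_reconstruct"]


class MatrixOperator:
    """Sparse-matrix forward operator mapping (n_z, n_y) volumes to stacked
    projections."""

    def __init__(self, matrix: sp.spmatrix, vol_shape: tuple[int, int]):
        self.matrix = matrix.tocsr()
        self.vol_shape = tuple(vol_shape)
        if self.matrix.shape[1] != int(np.prod(vol_shape)):
            raise ValueError("matrix columns do not match volume shape")

    def forward(self, volume: np.ndarray) -> np.ndarray:
        return np.asarray(self.matrix @ np.asarray(volume, float).ravel())

    def adjoint(self, proj: np.ndarray) -> np.ndarray:
        return np.asarray(self.matrix.T @ np.asarray(proj, float)).reshape(
            self.vol_shape
        )


class ABOperator:
    """Composition: blur each slice of the volume, then project (A·B)."""

    def __init__(self, projection_op: MatrixOperator, blur_op: BlurOperator):
        if blur_op.n_slices not in (1, projection_op.vol_shape[0]):
            raise ValueError("blur operator slice count does not match volume")
        self.projection_op = projection_op
        self.blur_op = blur_op
        self.vol_shape = projection_op.vol_shape

    def forward(self, volume: np.ndarray) -> np.ndarray:
        return self.projection_op.forward(self.blur_op.apply(volume))

    def adjoint(self, proj: np.ndarray) -> np.ndarray:
        return self.blur_op.apply(self.projection_op.adjoint(proj), adjoint=True)


def power_iteration(op, n_iter: int = 50, seed: int = 0) -> float:
    """Estimate L = largest eigenvalue of OpᵀOp (squared operator norm)."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(op.vol_shape)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        w = op.adjoint(op.forward(v))
        lam = float(np.linalg.norm(w.ravel()))
        if lam == 0:
            return 0.0
        v = w / lam
    return lam


def lsq_reconstruct(
    projections: np.ndarray,
    op,
    iters: int = 200,
    step: float | None = None,
    x0: np.ndarray | None = None,
    return_objective: bool = False,
):
    """Gradient descent on ``½‖Op v − y‖²`` from a zero (or given) start.

    Raises if the objective increases beyond round-off, which indicates a
    bad step size.
    """
    y = np.asarray(projections, float).ravel()
    if step is None:
        lam = power_iteration(op)
        if lam == 0:
            step = 1.0
        else:
            step = 1.0 / lam
    v = np.zeros(op.vol_shape) if x0 is None else np.array(x0, float)
    obj = []
    prev = None
    for _ in range(iters):
        r = op.forward(v) - y
        f = 0.5 * float(r @ r)
        if prev is not None and f > prev * (1 + 1e-9) + 1e-300:
            raise RuntimeError(
                f"objective increased ({prev:.6g} -> {f:.6g}); reduce the step size"
            )
        prev = f
        obj.append(f)
        v = v - step * op.adjoint(r)
    if return_objective:
        return v, np.asarray(obj)
    return v
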