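"""Minimal convolutional network toolkit (numpy, manual backprop).

Implements exactly what the noise-predicting denoiser needs: 3×3 "same"
convolutions, dense layers, ReLU, a sinusoidal step embedding, residual
blocks with per-channel step conditioning, and Adam.  The network is fully
convolutional (no attention, no resampling), so a trained model applies to
images of any size.  Gradients are hand-derived and checked against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "Dense", "EpsilonNet", "Adam", "sinusoidal_embedding"]


def sinusoidal_embedding(t_frac: np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal positional encoding of diffusion steps.

    ``t_frac`` is the step scaled to [0, 1]; returns (B, dim) features at
    geometrically spaced frequencies.
    """
    t = np.atleast_1d(np.asarray(t_frac, float)) * 1000.0
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


class Conv2d:
    """3×3 same-padding convolution with bias and optional dilation.

    Dilation d samples taps at offsets {−d, 0, d}, widening the receptive
    field at unchanged cost.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 zero_init: bool = False, dilation: int = 1,
                 dtype=np.float32):
        scale = 0.0 if zero_init else np.sqrt(2.0 / (c_in * 9))
        self.W = (rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.dilation = int(dilation)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        d = self.dilation
        B, Ci, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (d, d), (d, d)))
        y = np.zeros((B, self.W.shape[0], H, Wd), dtype=self.W.dtype)
        for ky in range(3):
            for kx in range(3):
                y += np.einsum(
                    "bihw,oi->bohw",
                    xp[:, :, ky * d : ky * d + H, kx * d : kx * d + Wd],
                    self.W[:, :, ky, kx],
                    optimize=True,
                )
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        d = self.dilation
        B, Ci, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (d, d), (d, d)))
        dxp = np.zeros_like(xp)
        for ky in range(3):
            for kx in range(3):
                patch = xp[:, :, ky * d : ky * d + H, kx * d : kx * d + Wd]
                self.gW[:, :, ky, kx] += np.einsum(
                    "bohw,bihw->oi", dy, patch, optimize=True
                )
                dxp[:, :, ky * d : ky * d + H, kx * d : kx * d + Wd] += np.einsum(
                    "bohw,oi->bihw", dy, self.W[:, :, ky, kx], optimize=True
                )
        self.gb += dy.sum(axis=(0, 2, 3))
        return dxp[:, :, d:-d, d:-d]

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.W = (rng.standard_normal((n_out, n_in)) * np.sqrt(1.0 / n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gW += dy.T @ self._x
        self.gb += dy.sum(axis=0)
        return dy @ self.W

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class EpsilonNet:
    """Time-conditioned residual CNN predicting the diffusion noise.

    Structure: input conv (1→C), ``n_blocks`` residual blocks — each adds a
    per-channel bias derived from the step embedding, then applies
    ReLU→conv→ReLU→conv and a skip connection — and a zero-initialized
    output conv (C→1).  Optional per-block dilations widen the receptive
    field at unchanged cost.  Weights default to float32 for speed;
    shape-preserving for any (H, W).
    """

    def __init__(self, channels: int = 16, n_blocks: int = 3, emb_dim: int = 32,
                 seed: int = 0, dilations: tuple[int, ...] | None = None,
                 dtype=np.float32):
        rng = np.random.default_rng(seed)
        if dilations is None:
            dilations = (1,) * n_blocks
        if len(dilations) != n_blocks:
            raise ValueError("need one dilation per block")
        self.channels = channels
        self.n_blocks = n_blocks
        self.emb_dim = emb_dim
        self.dtype = np.dtype(dtype)
        self.dilations = tuple(int(d) for d in dilations)
        self.conv_in = Conv2d(1, channels, rng, dtype=dtype)
        self.blocks = []
        for d in self.dilations:
            self.blocks.append(
                {
                    "dense": Dense(emb_dim, channels, rng, dtype=dtype),
                    "conv1": Conv2d(channels, channels, rng, dilation=d, dtype=dtype),
                    "conv2": Conv2d(channels, channels, rng, dilation=d, dtype=dtype),
                }
            )
        self.conv_out = Conv2d(channels, 1, rng, zero_init=True, dtype=dtype)

    # -- plumbing ---------------------------------------------------------
    def modules(self):
        mods = [self.conv_in]
        for blk in self.blocks:
            mods += [blk["dense"], blk["conv1"], blk["conv2"]]
        mods.append(self.conv_out)
        return mods

    def params(self):
        out = []
        for m in self.modules():
            out += m.params()
        return out

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.params()]

    # -- forward/backward -------------------------------------------------
    def forward(self, x: np.ndarray, t_frac: np.ndarray) -> np.ndarray:
        """x: (B, H, W) or (B, 1, H, W); t_frac: (B,) in [0, 1]."""
        squeeze = x.ndim == 3
        if squeeze:
            x = x[:, None]
        x = np.ascontiguousarray(x, dtype=self.dtype)
        emb = sinusoidal_embedding(t_frac, self.emb_dim).astype(self.dtype)
        self._cache = []
        h = self.conv_in.forward(x)
        for blk in self.blocks:
            tb = blk["dense"].forward(emb)
            a = h + tb[:, :, None, None]
            r1 = np.maximum(a, 0.0)
            c1 = blk["conv1"].forward(r1)
            r2 = np.maximum(c1, 0.0)
            c2 = blk["conv2"].forward(r2)
            self._cache.append((a, c1))
            h = h + c2
        self._pre_out = h
        y = self.conv_out.forward(np.maximum(h, 0.0))
        return y[:, 0] if squeeze else y

    def backward(self, dy: np.ndarray) -> None:
        if dy.ndim == 3:
            dy = dy[:, None]
        dy = np.ascontiguousarray(dy, dtype=self.dtype)
        dh = self.conv_out.backward(dy) * (self._pre_out > 0)
        for blk, (a, c1) in zip(reversed(self.blocks), reversed(self._cache)):
            dc2 = dh
            dr2 = blk["conv2"].backward(dc2) * (c1 > 0)
            dr1 = blk["conv1"].backward(dr2) * (a > 0)
            blk["dense"].backward(dr1.sum(axis=(2, 3)))
            dh = dh + dr1
        self.conv_in.backward(dh)

    def __call__(self, x: np.ndarray, t_frac: np.ndarray) -> np.ndarray:
        return self.forward(x, t_frac)

    # -- serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, (p, _) in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (p, _) in enumerate(self.params()):
            p[...] = state[f"p{i}"]


class Adam:
    """Adaptive-moment optimizer over (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)
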