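"""Denoising diffusion prior: schedule, training, DDIM sampling, score.

The forward process corrupts an image in T steps,
``x_t = √(1−β_t)·x_{t−1} + √β_t·ε``, equivalently
``x_t = √ᾱ_t·x_0 + √(1−ᾱ_t)·ε`` with ``ᾱ_t = Π_{s≤t}(1−β_s)``.  A
noise-predicting network ε_θ(x_t, t) is trained by mean-squared error
against the injected noise; deterministic DDIM sampling inverts the chain,
and the trained predictor yields the score via
``∇ log p(x_t) = −ε_θ(x_t, t)/√(1−ᾱ_t)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .nn import Adam, EpsilonNet

__all__ = [
    "NoiseSchedule",
    "make_schedule",
    "forward_diffuse",
    "TrainConfig",
    "Denoiser",
    "train_denoiser",
    "ddim_sample",
    "score_from_eps",
]


@dataclasses.dataclass(frozen=True)
class NoiseSchedule:
    """Variance schedule β_t and cumulative products ᾱ_t, t = 1..T.

    ``alpha_bar(0) = 1`` by convention; ``alpha_bar`` is strictly
    decreasing in t.
    """

    beta: np.ndarray  # (T,), beta[t-1] is β_t

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, float)
        if b.ndim != 1 or b.size < 1:
            raise ValueError("beta must be a 1D array with T >= 1")
        if np.any(b <= 0) or np.any(b >= 1):
            raise ValueError("beta values must lie in (0, 1)")
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "_abar", np.cumprod(1.0 - b))

    @property
    def T(self) -> int:
        return self.beta.size

    def alpha_bar(self, t) -> np.ndarray | float:
        """ᾱ_t for integer step(s) t in 0..T (ᾱ_0 = 1)."""
        t = np.asarray(t)
        if np.any(t < 0) or np.any(t > self.T):
            raise ValueError(f"t must be in 0..{self.T}")
        ab = np.concatenate([[1.0], self._abar])
        out = ab[t]
        return float(out) if out.ndim == 0 else out


def make_schedule(T: int = 1000, beta_start: float = 1e-4,
                  beta_end: float = 0.02) -> NoiseSchedule:
    """Linear β grid from ``beta_start`` to ``beta_end`` over T steps."""
    if not 0 < beta_start <= beta_end < 1:
        raise ValueError("require 0 < beta_start <= beta_end < 1")
    if T < 1:
        raise ValueError("T must be >= 1")
    return NoiseSchedule(np.linspace(beta_start, beta_end, T))


def forward_diffuse(x0: np.ndarray, t: int, schedule: NoiseSchedule,
                    noise: np.ndarray) -> np.ndarray:
    """Closed-form draw of x_t given x_0: ``√ᾱ_t·x0 + √(1−ᾱ_t)·noise``."""
    x0 = np.asarray(x0, float)
    noise = np.asarray(noise, float)
    if noise.shape != x0.shape:
        raise ValueError("noise must have the same shape as x0")
    ab = schedule.alpha_bar(int(t))
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * noise


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Denoiser training hyperparameters (desk scale by default).

    ``channels``/``n_blocks`` size the residual CNN; the larger
    configuration used at full scale (more scales/blocks/channels) is
    reachable by passing bigger numbers, at matching cost.
    """

    steps: int = 5000
    batch_size: int = 16
    lr: float = 1e-4
    patch_size: int = 32
    channels: int = 16
    n_blocks: int = 3
    emb_dim: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name != "seed" and getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


class Denoiser:
    """Trained noise predictor with its schedule and intensity mapping.

    Callable as ``denoiser(x_t, t)`` with x_t in the model's normalized
    [−1, 1] domain and integer step t in 1..T.  ``normalize`` /
    ``denormalize`` map raw slice intensities to and from that domain
    using the dataset-global range stored at training time.
    """

    def __init__(self, net: EpsilonNet, schedule: NoiseSchedule,
                 intensity_range: tuple[float, float]):
        lo, hi = intensity_range
        if not hi > lo:
            raise ValueError("intensity range must have hi > lo")
        self.net = net
        self.schedule = schedule
        self.intensity_range = (float(lo), float(hi))

    def __call__(self, x_t: np.ndarray, t: int | np.ndarray) -> np.ndarray:
        x_t = np.asarray(x_t, float)
        squeeze = x_t.ndim == 2
        if squeeze:
            x_t = x_t[None]
        t_arr = np.broadcast_to(np.asarray(t, float), (x_t.shape[0],))
        out = self.net(x_t, t_arr / self.schedule.T)
        return out[0] if squeeze else out

    def normalize(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.intensity_range
        return 2.0 * (np.asarray(x, float) - lo) / (hi - lo) - 1.0

    def denormalize(self, xn: np.ndarray) -> np.ndarray:
        lo, hi = self.intensity_range
        return (np.asarray(xn, float) + 1.0) * (hi - lo) / 2.0 + lo

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            beta=self.schedule.beta,
            lo=self.intensity_range[0],
            hi=self.intensity_range[1],
            channels=self.net.channels,
            n_blocks=self.net.n_blocks,
            emb_dim=self.net.emb_dim,
            dilations=np.asarray(self.net.dilations),
            **self.net.state_dict(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Denoiser":
        data = np.load(path)
        net = EpsilonNet(
            channels=int(data["channels"]),
            n_blocks=int(data["n_blocks"]),
            emb_dim=int(data["emb_dim"]),
            dilations=tuple(int(d) for d in data["dilations"]),
        )
        net.load_state_dict({k: data[k] for k in data.files if k.startswith("p")})
        return cls(
            net,
            NoiseSchedule(data["beta"]),
            (float(data["lo"]), float(data["hi"])),
        )


def train_denoiser(
    patches: np.ndarray,
    schedule: NoiseSchedule,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[Denoiser, np.ndarray]:
    """Train ε_θ on image patches by the noise-prediction MSE objective.

    ``patches`` are raw-intensity images (N, H, W); they are mapped to
    [−1, 1] by their global min/max, which is stored with the model.  Each
    step draws a patch batch, uniform steps t, Gaussian noise, and
    minimizes ``‖ε − ε_θ(√ᾱ_t x0 + √(1−ᾱ_t) ε, t)‖²`` with Adam.
    Returns the trained denoiser and the loss curve.
    """
    patches = np.asarray(patches, float)
    if patches.ndim != 3:
        raise ValueError("patches must be (N, H, W)")
    lo, hi = float(patches.min()), float(patches.max())
    if not hi > lo:
        # degenerate constant dataset: use a unit band around the value
        lo, hi = lo - 1.0, hi + 1.0
    xn = 2.0 * (patches - lo) / (hi - lo) - 1.0
    rng = np.random.default_rng(cfg.seed)
    net = EpsilonNet(cfg.channels, cfg.n_blocks, cfg.emb_dim, seed=cfg.seed)
    opt = Adam(net.params(), lr=cfg.lr)
    T = schedule.T
    ab = schedule.alpha_bar(np.arange(1, T + 1))
    losses = np.empty(cfg.steps)
    for it in range(cfg.steps):
        idx = rng.integers(0, xn.shape[0], cfg.batch_size)
        x0 = xn[idx]
        if cfg.patch_size < x0.shape[1]:
            i0 = rng.integers(0, x0.shape[1] - cfg.patch_size + 1)
            j0 = rng.integers(0, x0.shape[2] - cfg.patch_size + 1)
            x0 = x0[:, i0 : i0 + cfg.patch_size, j0 : j0 + cfg.patch_size]
        t = rng.integers(1, T + 1, cfg.batch_size)
        eps = rng.standard_normal(x0.shape)
        abt = ab[t - 1][:, None, None]
        x_t = np.sqrt(abt) * x0 + np.sqrt(1.0 - abt) * eps
        pred = net(x_t, t / T)
        diff = pred - eps
        loss = float(np.mean(diff**2))
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at step {it}")
        losses[it] = loss
        net.zero_grad()
        net.backward(2.0 * diff / diff.size)
        opt.step()
    return Denoiser(net, schedule, (lo, hi)), losses


def ddim_sample(
    denoiser,
    schedule: NoiseSchedule,
    x_T: np.ndarray,
    steps=None,
) -> np.ndarray:
    """Deterministic DDIM sampling from x_T down to the x_0 estimate.

    ``x_{t−1} = √ᾱ_{t−1}·(x_t − √(1−ᾱ_t)·ε_θ)/√ᾱ_t + √(1−ᾱ_{t−1})·ε_θ``.
    ``steps`` is a descending sequence of step indices (default T..1);
    ``denoiser`` is any callable (x_t, t) → predicted noise.
    """
    if steps is None:
        steps = range(schedule.T, 0, -1)
    steps = list(steps)
    if any(s2 >= s1 for s1, s2 in zip(steps, steps[1:])) or not steps:
        raise ValueError("steps must be a nonempty strictly descending sequence")
    x = np.asarray(x_T, float).copy()
    for i, t in enumerate(steps):
        t_prev = steps[i + 1] if i + 1 < len(steps) else 0
        ab_t = schedule.alpha_bar(t)
        ab_p = schedule.alpha_bar(t_prev)
        eps = denoiser(x, t)
        x0_pred = (x - np.sqrt(1.0 - ab_t) * eps) / np.sqrt(ab_t)
        x = np.sqrt(ab_p) * x0_pred + np.sqrt(1.0 - ab_p) * eps
    return x


def score_from_eps(denoiser, x_t: np.ndarray, t: int,
                   schedule: NoiseSchedule) -> np.ndarray:
    """Score estimate ``∇ log p(x_t) = −ε_θ(x_t, t)/√(1−ᾱ_t)``."""
    ab = schedule.alpha_bar(int(t))
    if ab >= 1.0:
        raise ZeroDivisionError("score undefined at t=0 (alpha_bar = 1)")
    return -np.asarray(denoiser(x_t, t), float) / np.sqrt(1.0 - ab)
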