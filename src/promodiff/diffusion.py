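"""Denoising diffusion probabilistic model (DDPM) over one-hot promoters.

The generator treats a one-hot encoded promoter (an L×4 matrix x₀) as a point
in ℝ^{L×4} and runs the standard two-phase DDPM Markov chain:

* **forward (noising)**: Gaussian noise is added over T steps with per-step
  variances β₁…β_T; by the Markov property the state at step t has the closed
  form ``x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε`` with ε ~ N(0, I) and
  ᾱ_t = ∏_{s≤t}(1−β_s);
* **reverse (denoising)**: a small 1-D convolutional residual network with a
  sinusoidal timestep embedding predicts ε from (x_t, t); it is trained by
  minimizing the mean absolute error (L1 loss) between true and predicted
  noise, with t drawn uniformly per example;
* **sampling**: ancestral sampling from x_T ~ N(0, I) down to x₀ using
  ``x_{t−1} = (x_t − β_t/√(1−ᾱ_t)·ε̂)/√α_t + σ_t·z`` with σ_t² = β_t, followed
  by per-row argmax decoding back to an A/T/C/G string.

Training is unsupervised (sequences only) and fully seeded: data shuffling,
timestep draws, noise draws and sampling each consume a named stream spawned
from one run seed, so a fixed seed reproduces losses, checkpoints and samples
bit-for-bit on one machine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Conv1d, Linear, Module, Parameter, Tensor, no_grad, relu
from .sequence_codec import (
    ConfigurationError,
    PromoterDataset,
    ValidationError,
    one_hot_decode,
    one_hot_encode_batch,
)

__all__ = [
    "NoiseSchedule",
    "build_schedule",
    "forward_noise",
    "DiffusionConfig",
    "NoisePredictor",
    "TrainingLog",
    "DiffusionGenerator",
    "train_ddpm",
]


# ---------------------------------------------------------------------------
# noise schedule


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step variances β_t and derived α_t, ᾱ_t tables (index 0 ↔ t=1)."""

    betas: np.ndarray

    @property
    def T(self) -> int:
        return len(self.betas)

    @property
    def alphas(self) -> np.ndarray:
        return 1.0 - self.betas

    @property
    def alpha_bars(self) -> np.ndarray:
        return np.cumprod(self.alphas)


def build_schedule(
    T: int = 1000,
    beta_start: float = 1e-4,
    beta_end: float = 0.02,
    shape: str = "linear",
) -> NoiseSchedule:
    """Linear β schedule from ``beta_start`` to ``beta_end`` over T steps."""
    if shape != "linear":
        raise ConfigurationError(f"unknown schedule shape {shape!r}")
    if T < 1:
        raise ConfigurationError(f"T must be ≥ 1, got {T}")
    if not 0.0 < beta_start <= beta_end < 1.0:
        raise ConfigurationError(
            f"need 0 < beta_start ≤ beta_end < 1, got [{beta_start}, {beta_end}]"
        )
    return NoiseSchedule(np.linspace(beta_start, beta_end, T))


def forward_noise(
    x0: np.ndarray, t: int | np.ndarray, schedule: NoiseSchedule, noise: np.ndarray
) -> np.ndarray:
    """Closed-form forward noising ``x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε``.

    ``t`` is 1-based (t=T is the fully noised endpoint) and may be an array
    matching the leading axis of a batched ``x0``.
    """
    t = np.asarray(t)
    if np.any(t < 1) or np.any(t > schedule.T):
        raise ValidationError(f"t outside [1, {schedule.T}]")
    abar = schedule.alpha_bars[t - 1]
    if x0.ndim == 3:  # batched: (m, L, 4) with per-example t
        abar = np.reshape(abar, (-1, 1, 1)) if abar.ndim else abar
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * noise


# ---------------------------------------------------------------------------
# noise-prediction network


def _sinusoidal_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Transformer-style sin/cos embedding of (1-based) timesteps."""
    half = dim // 2
    freqs = np.exp(-math.log(10000.0) * np.arange(half) / max(half - 1, 1))
    args = np.asarray(t, dtype=float)[:, None] * freqs[None, :]
    return np.concatenate([np.sin(args), np.cos(args)], axis=1)


class _ResBlock(Module):
    def __init__(self, channels: int, kernel: int, time_dim: int, rng):
        self.conv1 = Conv1d(channels, channels, kernel, rng)
        self.conv2 = Conv1d(channels, channels, kernel, rng)
        self.time_proj = Linear(time_dim, channels, rng)

    def __call__(self, h: Tensor, temb: Tensor) -> Tensor:
        b = h.shape[0]
        shift = self.time_proj(temb).reshape(b, 1, -1)
        inner = relu(self.conv1(h) + shift)
        return relu(h + self.conv2(inner))


class NoisePredictor(Module):
    """Conv-residual ε-predictor: (x_t as L×4 reals, t) → predicted noise.

    A learned per-position bias is added after the input convolution: plain
    convolutions are translation-equivariant, but promoter structure (the
    −10/−35 elements) is anchored to the TSS, so the network needs an
    explicit positional channel to denoise position-specific motifs.
    """

    def __init__(
        self,
        length: int,
        channels: int = 32,
        blocks: int = 2,
        kernel: int = 5,
        time_dim: int = 32,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.time_dim = time_dim
        self.time_mlp = Linear(time_dim, time_dim, rng)
        self.inp = Conv1d(4, channels, kernel, rng)
        self.pos_bias = Parameter(rng.normal(0.0, 0.02, size=(length, channels)))
        self.blocks = [_ResBlock(channels, kernel, time_dim, rng) for _ in range(blocks)]
        self.out = Conv1d(channels, 4, kernel, rng)

    def __call__(self, xt: np.ndarray | Tensor, t: np.ndarray) -> Tensor:
        x = xt if isinstance(xt, Tensor) else Tensor(xt)
        temb = relu(self.time_mlp(Tensor(_sinusoidal_embedding(t, self.time_dim))))
        h = relu(self.inp(x) + self.pos_bias)
        for block in self.blocks:
            h = block(h, temb)
        return self.out(h)


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class DiffusionConfig:
    """Hyperparameters of the generator; defaults are the package's full-run
    settings (T=1000 linear β 1e-4…0.02); tests use T=200 and fewer epochs."""

    T: int = 1000
    beta_start: float = 1e-4
    beta_end: float = 0.02
    channels: int = 32
    blocks: int = 2
    kernel: int = 5
    time_dim: int = 32
    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    checkpoint_every: int = 10
    rescale_signed: bool = False  # optionally map one-hot {0,1} → {−1,+1}
    seed: int = 0


@dataclass
class TrainingLog:
    """Per-epoch L1 losses and periodic parameter checkpoints."""

    epochs: list[int] = field(default_factory=list)
    train_l1: list[float] = field(default_factory=list)
    heldout_l1: list[float] = field(default_factory=list)
    checkpoints: dict[int, list[np.ndarray]] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_l1": self.train_l1,
                "heldout_l1": self.heldout_l1,
            }
        )


class DiffusionGenerator:
    """A trained DDPM: noise predictor + schedule + training log."""

    def __init__(
        self,
        predictor: NoisePredictor,
        schedule: NoiseSchedule,
        sequence_length: int,
        config: DiffusionConfig,
        log: TrainingLog,
    ):
        self.predictor = predictor
        self.schedule = schedule
        self.sequence_length = sequence_length
        self.config = config
        self.log = log

    # -- sampling -----------------------------------------------------------

    def _ancestral_sample(self, count: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        L = self.sequence_length
        betas = self.schedule.betas
        alphas = self.schedule.alphas
        abars = self.schedule.alpha_bars
        x = rng.standard_normal((count, L, 4))
        with no_grad():
            for t in range(self.schedule.T, 0, -1):
                i = t - 1
                eps = self.predictor(x, np.full(count, t)).data
                x = (x - betas[i] / math.sqrt(1.0 - abars[i]) * eps) / math.sqrt(
                    alphas[i]
                )
                if t > 1:
                    x = x + math.sqrt(betas[i]) * rng.standard_normal(x.shape)
        return x

    def sample_matrices(self, count: int, seed: int = 0) -> np.ndarray:
        """Raw x₀ matrices from ancestral sampling (before decoding)."""
        if count < 0:
            raise ConfigurationError(f"count must be ≥ 0, got {count}")
        if count == 0:
            return np.zeros((0, self.sequence_length, 4))
        return self._ancestral_sample(count, seed)

    def sample(self, count: int, seed: int = 0) -> list[str]:
        """Generate promoter sequences of the training length."""
        x0 = self.sample_matrices(count, seed)
        if self.config.rescale_signed:
            x0 = (x0 + 1.0) / 2.0
        return [one_hot_decode(m) for m in x0]

    def sample_at_checkpoint(self, epoch: int, count: int, seed: int = 0) -> list[str]:
        """Sample from the parameters saved at a given training epoch."""
        if epoch not in self.log.checkpoints:
            raise ValidationError(
                f"no checkpoint at epoch {epoch}; have {sorted(self.log.checkpoints)}"
            )
        current = self.predictor.state_dict()
        try:
            self.predictor.load_state_dict(self.log.checkpoints[epoch])
            return self.sample(count, seed)
        finally:
            self.predictor.load_state_dict(current)


def _l1(pred: Tensor, target: np.ndarray) -> Tensor:
    return (pred - Tensor(target)).abs().mean()


def train_ddpm(
    dataset: PromoterDataset,
    config: DiffusionConfig = DiffusionConfig(),
) -> DiffusionGenerator:
    """Train the ε-predictor on one-hot sequences with L1 loss.

    A ``val_fraction`` slice of the data is held out for generator validation;
    its (t, ε) draws are frozen once so the held-out L1 trajectory is directly
    comparable across epochs.  Checkpoints of the network parameters are kept
    every ``checkpoint_every`` epochs for training-trajectory evaluation.
    """
    if config.epochs < 1:
        raise ConfigurationError("epochs must be ≥ 1")
    if len(dataset) < 2:
        raise ValidationError("need at least 2 sequences to train")

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng_split, rng_init, rng_train, rng_val = (
        np.random.default_rng(s) for s in seeds
    )

    x_all = one_hot_encode_batch(dataset.sequences)
    if config.rescale_signed:
        x_all = 2.0 * x_all - 1.0
    n = len(x_all)
    perm = rng_split.permutation(n)
    n_val = max(1, int(round(n * config.val_fraction)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    x_train, x_val = x_all[train_idx], x_all[val_idx]

    schedule = build_schedule(config.T, config.beta_start, config.beta_end)
    predictor = NoisePredictor(
        dataset.sequence_length,
        config.channels,
        config.blocks,
        config.kernel,
        config.time_dim,
        seed=int(rng_init.integers(2**31)),
    )
    optimizer = Adam(predictor.parameters(), lr=config.learning_rate)

    # frozen validation corruption: same (t, ε) every epoch
    t_val = rng_val.integers(1, schedule.T + 1, size=len(x_val))
    eps_val = rng_val.standard_normal(x_val.shape)
    xt_val = forward_noise(x_val, t_val, schedule, eps_val)

    log = TrainingLog()
    for epoch in range(1, config.epochs + 1):
        order = rng_train.permutation(len(x_train))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = x_train[order[start : start + config.batch_size]]
            t = rng_train.integers(1, schedule.T + 1, size=len(batch))
            eps = rng_train.standard_normal(batch.shape)
            xt = forward_noise(batch, t, schedule, eps)
            optimizer.zero_grad()
            loss = _l1(predictor(xt, t), eps)
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
        if not np.isfinite(epoch_losses).all():
            raise ValidationError(f"training diverged at epoch {epoch}")
        with no_grad():
            val_loss = _l1(predictor(xt_val, t_val), eps_val).item()
        log.epochs.append(epoch)
        log.train_l1.append(float(np.mean(epoch_losses)))
        log.heldout_l1.append(val_loss)
        # epoch 1 is always checkpointed so training trajectories have a
        # near-untrained baseline to compare against
        if epoch == 1 or epoch % config.checkpoint_every == 0 or epoch == config.epochs:
            log.checkpoints[epoch] = predictor.state_dict()

    return DiffusionGenerator(
        predictor, schedule, dataset.sequence_length, config, log
    )
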