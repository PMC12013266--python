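"""Promoter strength regression: transformer encoder and CNN baseline.

The regression target is the promoter strength after base-10 log transform
and min–max scaling to [0, 1] (fitted on the training split and reused for
test data).  Two architectures share the loss and evaluation pathway:

* **transformer** — the three integer token streams (nucleotide 0–3,
  overlapping dinucleotide 4–23, position 0…L−1) are each mapped through a
  learned embedding table of dimension d_model and summed; a stack of
  encoder layers (multi-head scaled dot-product self-attention plus a
  position-wise feed-forward network, residual connections and layer norm)
  produces a sequence representation that is mean-pooled and passed through
  a linear head;
* **CNN baseline** — a small 1-D convolutional network over the one-hot
  encoding, global-mean-pooled into the same linear head.

Training minimizes the composite loss ``w_mse·MSE + w_pcc·(1 − PCC)``; the
Pearson term rewards linear association between predicted and measured
strengths directly, the MSE term anchors the scale.  For a batch whose
predictions are (numerically) constant the PCC term is undefined and is
skipped for that batch with a logged warning.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import (
    Adam,
    Embedding,
    LayerNorm,
    Linear,
    Conv1d,
    Module,
    Tensor,
    dropout,
    no_grad,
    relu,
    softmax,
)
from .metrics import pcc
from .sequence_codec import (
    ConfigurationError,
    NormalizationParams,
    PromoterDataset,
    ValidationError,
    encode_dinucleotide_tokens,
    encode_position_tokens,
    encode_sequence_tokens,
    normalize_strengths,
    denormalize_strengths,
    one_hot_encode_batch,
    TOKEN_VOCABULARY,
)

logger = logging.getLogger(__name__)

__all__ = [
    "self_attention",
    "pcc",
    "combined_loss",
    "PredictorConfig",
    "TrainedPredictor",
    "train_predictor",
    "train_cnn_baseline",
    "predict_strength",
    "evaluate_predictor",
]


# ---------------------------------------------------------------------------
# attention primitive


def self_attention(
    Q: np.ndarray | Tensor,
    K: np.ndarray | Tensor,
    V: np.ndarray | Tensor,
    mask: np.ndarray | None = None,
    return_weights: bool = False,
):
    """Scaled dot-product attention ``softmax(QKᵀ/√d_k) · V``.

    Shapes: Q, K are (…, n, d_k) and V is (…, n, d_v); an optional boolean
    mask (…, n, n) marks positions allowed to attend (False → weight 0).
    Rows of the attention weight matrix sum to 1.  Accepts plain arrays (and
    then returns arrays) or autodiff tensors inside a model.
    """
    as_array = not isinstance(Q, Tensor)
    q = Tensor._wrap(Q)
    k = Tensor._wrap(K)
    v = Tensor._wrap(V)
    if q.shape[-1] != k.shape[-1] or q.shape[:-1] != k.shape[:-1]:
        raise ValidationError(f"Q/K shape mismatch: {q.shape} vs {k.shape}")
    if k.shape[-2] != v.shape[-2]:
        raise ValidationError(f"K/V length mismatch: {k.shape} vs {v.shape}")
    d_k = q.shape[-1]
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (
        1.0 / math.sqrt(d_k)
    )
    if mask is not None:
        scores = scores + Tensor(np.where(mask, 0.0, -1e30))
    weights = softmax(scores)
    out = weights @ v
    if as_array:
        out, weights = out.data, weights.data
    return (out, weights) if return_weights else out


# ---------------------------------------------------------------------------
# losses


def _mse(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((np.asarray(x, float) - np.asarray(y, float)) ** 2))


def combined_loss(
    pred: Sequence[float] | np.ndarray,
    target: Sequence[float] | np.ndarray,
    w_mse: float = 1.0,
    w_pcc: float = 1.0,
) -> float:
    """``w_mse·MSE + w_pcc·(1 − PCC)``; zero iff pred == target (w_mse > 0)."""
    if w_mse < 0 or w_pcc < 0 or (w_mse == 0 and w_pcc == 0):
        raise ConfigurationError("loss weights must be ≥ 0 and not both 0")
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.shape != target.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {target.shape}")
    total = w_mse * _mse(pred, target)
    if w_pcc > 0:
        if np.ptp(pred) == 0.0:
            logger.warning("constant predictions in batch; skipping PCC term")
        else:
            total += w_pcc * (1.0 - pcc(pred, target))
    return total


def _loss_tensor(pred: Tensor, target: np.ndarray, w_mse: float, w_pcc: float) -> Tensor:
    """Differentiable composite loss on a (B,) prediction tensor."""
    t = Tensor(target)
    diff = pred - t
    loss = (diff * diff).mean() * w_mse
    if w_pcc > 0 and np.ptp(pred.data) > 1e-12:
        pd = pred - pred.mean()
        td = t - t.mean()
        denom = ((pd * pd).sum() * (td * td).sum()).sqrt()
        loss = loss + (1.0 - (pd * td).sum() / denom) * w_pcc
    elif w_pcc > 0:
        logger.warning("constant predictions in batch; skipping PCC term")
    return loss


# ---------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class PredictorConfig:
    """Shared training settings plus per-architecture hyperparameters."""

    d_model: int = 64
    heads: int = 4
    layers: int = 2
    ff_width: int = 128
    dropout: float = 0.1
    cnn_channels: int = 32
    cnn_kernel: int = 5
    cnn_layers: int = 2
    w_mse: float = 1.0
    w_pcc: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 40
    batch_size: int = 64
    patience: int = 20
    val_fraction: float = 0.1
    pseudocount: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.heads != 0:
            raise ConfigurationError("d_model must be divisible by heads")
        if self.w_mse < 0 or self.w_pcc < 0 or (self.w_mse == 0 and self.w_pcc == 0):
            raise ConfigurationError("loss weights must be ≥ 0 and not both 0")


class _MultiHeadAttention(Module):
    def __init__(self, d_model: int, heads: int, rng):
        self.heads = heads
        self.d_head = d_model // heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, n, d = x.shape

        def split(t: Tensor) -> Tensor:
            return t.reshape(b, n, self.heads, self.d_head).transpose(0, 2, 1, 3)

        out = self_attention(split(self.wq(x)), split(self.wk(x)), split(self.wv(x)))
        return self.wo(out.transpose(0, 2, 1, 3).reshape(b, n, d))


class _EncoderLayer(Module):
    def __init__(self, d_model: int, heads: int, ff_width: int, rng):
        self.attn = _MultiHeadAttention(d_model, heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ff_width, rng)
        self.ff2 = Linear(ff_width, d_model, rng)
        self.ln2 = LayerNorm(d_model)

    def __call__(self, x: Tensor, drop_rate: float, rng) -> Tensor:
        h = self.ln1(x + dropout(self.attn(x), drop_rate, rng))
        return self.ln2(h + dropout(self.ff2(relu(self.ff1(h))), drop_rate, rng))


class TransformerRegressor(Module):
    def __init__(self, length: int, config: PredictorConfig, seed: int):
        rng = np.random.default_rng(seed)
        d = config.d_model
        self.config = config
        self.emb_seq = Embedding(4, d, rng)
        self.emb_dinuc = Embedding(TOKEN_VOCABULARY, d, rng)
        self.emb_pos = Embedding(length, d, rng)
        self.encoder = [
            _EncoderLayer(d, config.heads, config.ff_width, rng)
            for _ in range(config.layers)
        ]
        self.head = Linear(d, 1, rng)

    def __call__(self, tokens: dict[str, np.ndarray], drop_rate: float = 0.0, rng=None) -> Tensor:
        x = (
            self.emb_seq(tokens["seq"])
            + self.emb_dinuc(tokens["dinuc"])
            + self.emb_pos(tokens["pos"])
        )
        for layer in self.encoder:
            x = layer(x, drop_rate, rng)
        pooled = x.mean(axis=1)
        b = pooled.shape[0]
        return self.head(pooled).reshape(b)


class CNNRegressor(Module):
    def __init__(self, length: int, config: PredictorConfig, seed: int):
        rng = np.random.default_rng(seed)
        c = config.cnn_channels
        self.convs = [Conv1d(4, c, config.cnn_kernel, rng)] + [
            Conv1d(c, c, config.cnn_kernel, rng)
            for _ in range(config.cnn_layers - 1)
        ]
        self.head = Linear(c, 1, rng)

    def __call__(self, tokens: dict[str, np.ndarray], drop_rate: float = 0.0, rng=None) -> Tensor:
        h = Tensor(tokens["onehot"])
        for conv in self.convs:
            h = relu(conv(h))
            if drop_rate:
                h = dropout(h, drop_rate, rng)
        pooled = h.mean(axis=1)
        b = pooled.shape[0]
        return self.head(pooled).reshape(b)


def _featurize(sequences: Sequence[str], arch: str) -> dict[str, np.ndarray]:
    if arch == "cnn":
        return {"onehot": one_hot_encode_batch(sequences)}
    length = len(sequences[0])
    pos = encode_position_tokens(length)
    return {
        "seq": np.stack([encode_sequence_tokens(s) for s in sequences]),
        "dinuc": np.stack([encode_dinucleotide_tokens(s) for s in sequences]),
        "pos": np.broadcast_to(pos, (len(sequences), length)),
    }


def _batch(tokens: dict[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
    return {k: v[idx] for k, v in tokens.items()}


# ---------------------------------------------------------------------------
# trained-model facade


@dataclass
class TrainedPredictor:
    """A fitted regressor plus the normalization fitted on its training data."""

    model: Module
    architecture: str  # "transformer" | "cnn"
    sequence_length: int
    norm_params: NormalizationParams
    config: PredictorConfig

    def predict(self, sequences: Sequence[str], scale: str = "normalized") -> np.ndarray:
        """Predict strengths; ``scale`` is "normalized" (training scale,
        nominally [0, 1]) or "raw" (inverse of the log/min-max transform)."""
        if not sequences:
            return np.zeros(0)
        bad = [s for s in sequences if len(s) != self.sequence_length]
        if bad:
            raise ValidationError(
                f"{len(bad)} sequences do not match training length "
                f"{self.sequence_length}"
            )
        tokens = _featurize(list(sequences), self.architecture)
        preds = []
        with no_grad():
            for start in range(0, len(sequences), 512):
                idx = np.arange(start, min(start + 512, len(sequences)))
                preds.append(self.model(_batch(tokens, idx)).data)
        out = np.concatenate(preds)
        if scale == "raw":
            return denormalize_strengths(out, self.norm_params)
        if scale != "normalized":
            raise ConfigurationError(f"unknown scale {scale!r}")
        return out

    # -- persistence (plain JSON so model files stay text) ------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "architecture": self.architecture,
            "sequence_length": self.sequence_length,
            "norm_params": asdict(self.norm_params),
            "config": asdict(self.config),
            "state": [p.tolist() for p in self.model.state_dict()],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedPredictor":
        payload = json.loads(Path(path).read_text())
        config = PredictorConfig(**payload["config"])
        length = payload["sequence_length"]
        arch = payload["architecture"]
        model_cls = TransformerRegressor if arch == "transformer" else CNNRegressor
        model = model_cls(length, config, seed=0)
        model.load_state_dict([np.array(s) for s in payload["state"]])
        return cls(
            model,
            arch,
            length,
            NormalizationParams(**payload["norm_params"]),
            config,
        )


def predict_strength(
    model: TrainedPredictor, sequences: Sequence[str], scale: str = "normalized"
) -> np.ndarray:
    """Functional alias for :meth:`TrainedPredictor.predict`."""
    return model.predict(sequences, scale=scale)


# ---------------------------------------------------------------------------
# training


def _train(
    train: PromoterDataset, config: PredictorConfig, architecture: str
) -> TrainedPredictor:
    if not train.has_strengths:
        raise ValidationError("training records must all carry strengths")
    y_all, norm_params = normalize_strengths(
        train.strengths, pseudocount=config.pseudocount
    )
    tokens_all = _featurize(train.sequences, architecture)

    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_split, rng_init, rng_train = (np.random.default_rng(s) for s in seeds)

    n = len(train)
    perm = rng_split.permutation(n)
    n_val = max(1, int(round(n * config.val_fraction)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    model_cls = TransformerRegressor if architecture == "transformer" else CNNRegressor
    model = model_cls(
        train.sequence_length, config, seed=int(rng_init.integers(2**31))
    )
    optimizer = Adam(model.parameters(), lr=config.learning_rate)

    best_val = math.inf
    best_state = model.state_dict()
    stale = 0
    for epoch in range(config.epochs):
        order = train_idx[rng_train.permutation(len(train_idx))]
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:
                continue
            optimizer.zero_grad()
            pred = model(_batch(tokens_all, idx), config.dropout, rng_train)
            loss = _loss_tensor(pred, y_all[idx], config.w_mse, config.w_pcc)
            loss.backward()
            optimizer.step()
        with no_grad():
            val_pred = model(_batch(tokens_all, val_idx)).data
        val_loss = combined_loss(val_pred, y_all[val_idx], config.w_mse, config.w_pcc)
        if not math.isfinite(val_loss):
            raise ValidationError(f"training diverged at epoch {epoch + 1}")
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.load_state_dict(best_state)
    return TrainedPredictor(
        model, architecture, train.sequence_length, norm_params, config
    )


def train_predictor(
    train: PromoterDataset, config: PredictorConfig = PredictorConfig()
) -> TrainedPredictor:
    """Fit the transformer regressor on a labelled training set."""
    return _train(train, config, "transformer")


def train_cnn_baseline(
    train: PromoterDataset, config: PredictorConfig = PredictorConfig()
) -> TrainedPredictor:
    """Fit the one-hot CNN baseline with the same loss and evaluation path."""
    return _train(train, config, "cnn")


def evaluate_predictor(model: TrainedPredictor, test: PromoterDataset) -> float:
    """PCC between predictions and normalized measured strengths on a test set.

    The test strengths are normalized with the *training* min/max so both
    axes live on the model's output scale.
    """
    if len(test) < 2:
        raise ValidationError("evaluation needs at least 2 records")
    y, _ = normalize_strengths(
        test.strengths, model.norm_params, pseudocount=model.config.pseudocount
    )
    preds = model.predict(test.sequences)
    return pcc(preds, y)
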