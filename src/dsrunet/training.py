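"""Training protocol: Adam on the deep-supervision MAE loss.

Defaults follow the full-scale protocol (Adam, learning rate 1e-4, batch
size 256, up to 100 epochs, early stopping after 10 epochs without
validation improvement, MAE loss with MSE as an additional monitored
metric).  :meth:`TrainConfig.desk` returns a desk-scale profile (batch 32,
higher learning rate, few epochs) sized for single-CPU experimentation.

Early stopping monitors the composite validation loss (all supervision
heads); "improvement" means a strict decrease of at least ``min_delta``.
The parameters from the best validation epoch are restored on exit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nn.autodiff import Tensor, no_grad
from .nn.model import DSRUnet, ModelOutputs, deep_supervision_loss, save_checkpoint
from .records import SegmentPair, stack_segments

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "Adam", "train", "predict"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 256
    max_epochs: int = 100
    early_stop_patience: int = 10
    min_delta: float = 1e-6
    grad_clip: float | None = None  # global-norm clipping threshold
    lr_decay_factor: float = 1.0    # step decay: lr *= factor every ...
    lr_decay_every: int = 0         # ... this many epochs (0 = constant lr)
    seed: int = 0
    checkpoint_path: str | None = None

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.early_stop_patience >= self.max_epochs:
            # a patience that can never trigger is almost always a config slip
            logger.warning(
                "early_stop_patience (%d) >= max_epochs (%d): early stopping cannot trigger",
                self.early_stop_patience, self.max_epochs,
            )

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """Single-CPU profile for small synthetic experiments."""
        defaults = dict(learning_rate=1e-3, batch_size=16, max_epochs=10,
                        early_stop_patience=5, grad_clip=1.0,
                        lr_decay_factor=0.5, lr_decay_every=3)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    head_loss: list[list[float]] = field(default_factory=list)  # per-epoch, per-head
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


class Adam:
    """Adam optimizer (bias-corrected first/second moments)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _clip_grad_norm(params: Sequence[Tensor], max_norm: float) -> float:
    """Rescale gradients in place so their global L2 norm is <= max_norm."""
    total = np.sqrt(sum(
        float(np.sum(p.grad ** 2)) for p in params if p.grad is not None
    ))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


def _evaluate_split(model: DSRUnet, x: np.ndarray, y: np.ndarray,
                    weights, batch_size: int) -> tuple[float, float, float]:
    """Composite loss, main-head MSE and main-head MAE over one split."""
    model.eval()
    n = x.shape[0]
    tot_loss = tot_mse = tot_mae = 0.0
    with no_grad():
        for lo in range(0, n, batch_size):
            xb, yb = x[lo:lo + batch_size], y[lo:lo + batch_size]
            out = model.forward(xb)
            loss, _ = deep_supervision_loss(out, yb, weights)
            err = out.main.data - yb
            w = xb.shape[0]
            tot_loss += float(loss.data) * w
            tot_mse += float(np.mean(err ** 2)) * w
            tot_mae += float(np.mean(np.abs(err))) * w
    model.train()
    return tot_loss / n, tot_mse / n, tot_mae / n


def train(
    model: DSRUnet,
    train_set: Sequence[SegmentPair],
    val_set: Sequence[SegmentPair],
    cfg: TrainConfig,
) -> tuple[dict, TrainHistory]:
    """Fit the model; returns (best parameter state, history).

    The best-validation parameters are restored into ``model`` before
    returning; if ``cfg.checkpoint_path`` is set the checkpoint is also
    written to disk (with the segments' normalization constants as meta).
    """
    if not len(train_set) or not len(val_set):
        raise ValueError("train and validation sets must be non-empty")
    x_tr, y_tr = stack_segments(train_set)
    x_va, y_va = stack_segments(val_set)
    weights = model.cfg.supervision_weights
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    history = TrainHistory()
    best_loss = np.inf
    best_state: dict | None = None
    epochs_since_best = 0

    for epoch in range(cfg.max_epochs):
        if cfg.lr_decay_every > 0:
            opt.lr = cfg.learning_rate * cfg.lr_decay_factor ** (
                epoch // cfg.lr_decay_every
            )
        model.train()
        perm = rng.permutation(len(train_set))
        ep_loss = 0.0
        ep_heads = None
        n_batches = 0
        for lo in range(0, len(perm), cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            out = model.forward(x_tr[idx])
            loss, per_head = deep_supervision_loss(out, y_tr[idx], weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch + 1} "
                    f"(batch {n_batches}); try a lower learning rate"
                )
            model.zero_grad()
            loss.backward()
            if cfg.grad_clip is not None:
                _clip_grad_norm(model.parameters(), cfg.grad_clip)
            opt.step()
            ep_loss += float(loss.data)
            ep_heads = per_head if ep_heads is None else [
                a + b for a, b in zip(ep_heads, per_head)
            ]
            n_batches += 1
        ep_loss /= n_batches
        ep_heads = [h / n_batches for h in ep_heads]

        val_loss, val_mse, val_mae = _evaluate_split(
            model, x_va, y_va, weights, cfg.batch_size
        )
        history.train_loss.append(ep_loss)
        history.val_loss.append(val_loss)
        history.val_mse.append(val_mse)
        history.val_mae.append(val_mae)
        history.head_loss.append(ep_heads)
        logger.info(
            "epoch %d: train %.5f  val %.5f (mse %.5f, mae %.5f)",
            epoch + 1, ep_loss, val_loss, val_mse, val_mae,
        )

        if val_loss < best_loss - cfg.min_delta:
            best_loss = val_loss
            history.best_epoch = epoch
            best_state = {
                "params": {n: p.data.copy() for n, p in model.named_parameters()},
                "buffers": {n: b.copy() for n, b in model.named_buffers()},
            }
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.early_stop_patience:
                history.stop_reason = (
                    f"early stop: no validation improvement for "
                    f"{cfg.early_stop_patience} epochs"
                )
                break
    if not history.stop_reason:
        history.stop_reason = "reached max_epochs"

    if best_state is not None:
        params = dict(model.named_parameters())
        for n, d in best_state["params"].items():
            params[n].data[...] = d
        buffers = dict(model.named_buffers())
        for n, d in best_state["buffers"].items():
            buffers[n][...] = d
    if cfg.checkpoint_path:
        seg0 = train_set[0]
        save_checkpoint(model, cfg.checkpoint_path, meta={
            "abp_mu": seg0.norm_mu, "abp_sigma": seg0.norm_sigma,
            "best_epoch": history.best_epoch,
        })
    return best_state or {}, history


def predict(
    model: DSRUnet,
    segments: Sequence[SegmentPair],
    batch_size: int = 64,
) -> np.ndarray:
    """Predict ABP waveforms in mmHg for a segment collection.

    Applies each segment's stored inverse normalization, so the output is on
    the mmHg scale regardless of how the targets were standardized.  Batch
    composition does not affect per-segment results (eval mode).
    """
    if not segments:
        return np.empty((0, 0))
    x, _ = stack_segments(segments)
    if x.shape[1] != model.cfg.input_len:
        raise ValueError(
            f"segment length {x.shape[1]} != model input_len {model.cfg.input_len}"
        )
    preds = np.concatenate([
        model.predict_batch(x[lo:lo + batch_size])
        for lo in range(0, x.shape[0], batch_size)
    ])
    mu = np.array([s.norm_mu for s in segments])[:, None]
    sigma = np.array([s.norm_sigma for s in segments])[:, None]
    return preds * sigma + mu
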