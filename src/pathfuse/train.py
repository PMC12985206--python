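"""Fixed training protocol: AdamW, warm-up, plateau scheduling, clipping, early stop.

The protocol is deliberately fixed (no data-driven hyperparameter search):
AdamW with decoupled weight decay at initial learning rate 0.01, a linear
warm-up, reduce-on-plateau scheduling (factor 0.5, patience 5), global
gradient-norm clipping at L2 = 1.0, early stopping after 10 consecutive
epochs without validation-loss improvement (best weights restored), and
batch size 128.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, f1_score

from .nn import FusionNetwork, Tensor

logger = logging.getLogger(__name__)

__all__ = ["TrainProtocol", "AdamW", "bce_with_logits", "train", "evaluate"]


@dataclass
class TrainProtocol:
    """Fixed optimization hyperparameters, constant across folds and tasks."""

    initial_lr: float = 0.01
    weight_decay: float = 0.01
    warmup_epochs: int = 5
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    clip_norm: float = 1.0
    early_stop_patience: int = 10
    batch_size: int = 128
    max_epochs: int = 200
    n_restarts: int = 3  # random inits per fold; best validation loss kept

    def __post_init__(self):
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be > 0")


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * self.weight_decay * p.data
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def clip_global_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum((p.grad**2).sum() for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
        return max_norm
    return float(total)


def bce_with_logits(logit: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy on raw logits."""
    y = Tensor(np.asarray(y, dtype=np.float64))
    return (logit.softplus() - y * logit).mean()


def _forward_loss(model: FusionNetwork, xs, y, training=False, rng=None):
    out = model([Tensor(x) for x in xs], training=training, rng=rng)
    return bce_with_logits(out["logit"], y), out


def train(
    model: FusionNetwork,
    train_xs: list[np.ndarray],
    train_y: np.ndarray,
    val_xs: list[np.ndarray],
    val_y: np.ndarray,
    protocol: TrainProtocol | None = None,
    seed: int = 0,
) -> dict:
    """Train in place under the fixed protocol; returns the training history.

    The learning rate ramps linearly over the warm-up epochs, halves after
    ``plateau_patience`` epochs without validation-loss improvement, and
    training halts after ``early_stop_patience`` consecutive non-improving
    epochs with the best-validation-loss weights restored.
    """
    protocol = protocol or TrainProtocol()
    if len(train_y) == 0 or len(val_y) == 0:
        raise ValueError("empty training or validation split")
    if set(np.unique(train_y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    rng = np.random.default_rng(seed)
    params = model.parameters()
    opt = AdamW(params, protocol.initial_lr, protocol.weight_decay)
    n = len(train_y)
    base_lr = protocol.initial_lr
    lr_scale = 1.0
    best_val = np.inf
    best_state = model.state_dict()
    plateau_count = 0
    stop_count = 0
    history = {"train_loss": [], "val_loss": [], "lr": [], "grad_norm": [],
               "early_stop_epoch": None, "lr_reductions": 0}

    for epoch in range(protocol.max_epochs):
        warm = min(1.0, (epoch + 1) / max(protocol.warmup_epochs, 1))
        opt.lr = base_lr * warm * lr_scale
        order = rng.permutation(n)
        epoch_loss = 0.0
        max_norm_seen = 0.0
        for start in range(0, n, protocol.batch_size):
            idx = order[start:start + protocol.batch_size]
            loss, _ = _forward_loss(
                model, [x[idx] for x in train_xs], train_y[idx], training=True, rng=rng
            )
            opt.zero_grad()
            loss.backward()
            norm = clip_global_norm(params, protocol.clip_norm)
            max_norm_seen = max(max_norm_seen, norm)
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        val_loss, _ = _forward_loss(model, val_xs, val_y, training=False)
        val_loss = float(val_loss.data)
        history["train_loss"].append(epoch_loss / n)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        history["grad_norm"].append(max_norm_seen)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()
            plateau_count = 0
            stop_count = 0
        else:
            plateau_count += 1
            stop_count += 1
            if plateau_count >= protocol.plateau_patience:
                lr_scale *= protocol.plateau_factor
                plateau_count = 0
                history["lr_reductions"] += 1
                logger.info("epoch %d: plateau, lr scaled to %.2g x base", epoch + 1, lr_scale)
            if stop_count >= protocol.early_stop_patience:
                history["early_stop_epoch"] = epoch + 1
                logger.info("early stop at epoch %d", epoch + 1)
                break
    model.load_state_dict(best_state)
    return history


def evaluate(predictions: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Accuracy and class-support-weighted F1 for binary predictions."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    acc = accuracy_score(labels, predictions)
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class label vector; F1 zero-division guarded to 0",
                      stacklevel=2)
    f1 = f1_score(labels, predictions, average="weighted", zero_division=0)
    return float(acc), float(f1)


def predict_proba(model: FusionNetwork, xs: list[np.ndarray]) -> np.ndarray:
    out = model([Tensor(x) for x in xs], training=False)
    return 1.0 / (1.0 + np.exp(-out["logit"].data))
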