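"""Joint training of the backbone and every exit head.

All M exit classifiers are optimized together against a layer-cost-weighted
average of per-exit cross-entropies,

    L = sum_m w_m * CE_m / sum_m w_m,

where CE_m = -log p_m[label].  The default weighting w_m = m reflects the
relative inference cost of reaching exit m (m transformer blocks executed);
a uniform scheme is retained as an ablation switch.  The loss is invariant
to rescaling all weights by a positive constant.

Optimization uses Adam, implemented here on the model's NumPy parameter
dict, with an optional early stop when the epoch loss plateaus.  Training
is bit-reproducible for a fixed seed on a given machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .model import MultiExitTransformer

__all__ = ["LossWeights", "TrainConfig", "joint_loss", "train", "TrainHistory"]

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class LossWeights:
    """Per-exit loss weights w_1..w_M."""

    weights: tuple[float, ...]
    scheme: Literal["linear_cost", "uniform", "custom"] = "custom"

    def __post_init__(self) -> None:
        if len(self.weights) == 0 or any(w <= 0 for w in self.weights):
            raise ConfigurationError("loss weights must be positive and non-empty")

    @classmethod
    def linear_cost(cls, num_layers: int) -> "LossWeights":
        """w_m = m: exits that cost more layers weigh more."""
        return cls(tuple(float(m) for m in range(1, num_layers + 1)), "linear_cost")

    @classmethod
    def uniform(cls, num_layers: int) -> "LossWeights":
        return cls((1.0,) * num_layers, "uniform")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 15
    seed: int = 0
    # stop when the epoch loss improves by less than rel_tol for
    # plateau_patience consecutive epochs, or falls below loss_floor
    # (converged for all practical purposes on a classification task)
    plateau_patience: int = 3
    plateau_rel_tol: float = 1e-4
    loss_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ConfigurationError("batch_size, epochs >= 1 and learning_rate > 0")


@dataclass
class TrainHistory:
    """Per-epoch training log."""

    epochs: list[int] = field(default_factory=list)
    mean_joint_loss: list[float] = field(default_factory=list)
    per_exit_accuracy: list[np.ndarray] = field(default_factory=list)
    early_stopped: bool = False

    def to_frame(self) -> pd.DataFrame:
        M = len(self.per_exit_accuracy[0]) if self.per_exit_accuracy else 0
        rows = {
            "epoch": self.epochs,
            "mean_joint_loss": self.mean_joint_loss,
            "early_stopped": [self.early_stopped] * len(self.epochs),
        }
        for m in range(M):
            rows[f"exit{m + 1}_accuracy"] = [a[m] for a in self.per_exit_accuracy]
        return pd.DataFrame(rows)


def joint_loss(trajectory, label: int, w: LossWeights) -> float:
    """Weighted average of per-exit cross-entropies for one sample.

    ``trajectory`` is the (M, K) array of per-layer distributions; each
    exit contributes CE_m = -log p_m[label], floored at 1e-12 inside the
    logarithm so a confidently wrong head yields a large finite loss.
    """
    traj = np.asarray(trajectory, dtype=float)
    weights = w.as_array()
    if traj.ndim != 2 or traj.shape[0] != weights.size:
        raise ConfigurationError(
            f"trajectory has {traj.shape[0] if traj.ndim == 2 else '?'} layers, "
            f"weights have {weights.size}"
        )
    if not 0 <= label < traj.shape[1]:
        raise DataError(f"label {label} outside class space of size {traj.shape[1]}")
    ce = -np.log(np.maximum(traj[:, label], _PROB_FLOOR))
    return float((weights * ce).sum() / weights.sum())


class Adam:
    """Adam over a dict of NumPy parameter arrays."""

    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def train(
    model: MultiExitTransformer,
    corpus,
    tcfg: TrainConfig,
    w: Optional[LossWeights] = None,
) -> TrainHistory:
    """Jointly optimize backbone and all exit heads; returns the loss history.

    ``corpus`` is anything with ``tokens`` (N, T) and ``labels`` (N,)
    attributes, or a ``(tokens, labels)`` pair.  The model is updated in
    place; backbone and head parameters are trained once and reused across
    every exit strategy afterwards.
    """
    tokens, labels = _unpack_corpus(corpus)
    n = tokens.shape[0]
    if n == 0:
        raise DataError("training corpus is empty")
    if labels.min() < 0 or labels.max() >= model.cfg.num_classes:
        raise DataError("label outside the model's class space")
    if w is None:
        w = LossWeights.linear_cost(model.cfg.num_layers)
    weights = w.as_array()
    if weights.size != model.cfg.num_layers:
        raise ConfigurationError("loss weights must have one entry per layer")

    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(model.params, lr=tcfg.learning_rate)
    history = TrainHistory()
    best = np.inf
    stall = 0
    for epoch in range(1, tcfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        correct = np.zeros(model.cfg.num_layers, dtype=np.int64)
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            loss, grads, batch_correct = model.joint_loss_and_grads(
                tokens[idx], labels[idx], weights
            )
            opt.step(model.params, grads)
            losses.append(loss * idx.size)
            correct += batch_correct
        epoch_loss = float(np.sum(losses) / n)
        history.epochs.append(epoch)
        history.mean_joint_loss.append(epoch_loss)
        history.per_exit_accuracy.append(correct / n)
        if epoch_loss < tcfg.loss_floor:
            history.early_stopped = True
            break
        if epoch_loss < best * (1.0 - tcfg.plateau_rel_tol):
            best = epoch_loss
            stall = 0
        else:
            stall += 1
            if stall >= tcfg.plateau_patience:
                history.early_stopped = True
                break
    return history


def _unpack_corpus(corpus):
    if hasattr(corpus, "tokens") and hasattr(corpus, "labels"):
        return np.asarray(corpus.tokens), np.asarray(corpus.labels)
    tokens, labels = corpus
    return np.asarray(tokens), np.asarray(labels)
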