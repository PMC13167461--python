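"""Deployment modes for a trained multi-exit model.

*Budgeted* mode fixes one exit layer m* for every query — the right choice
when the compute budget is known up front.  *Dynamic* mode lets each input
choose its own exit at run time via an exit policy, so simple inputs leave
early and hard ones ride deeper.  Both operate per instance (batch size 1),
mirroring deployment where requests arrive one at a time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DataError
from .model import MultiExitTransformer
from .policy import ExitTrace, PolicyConfig

__all__ = [
    "BudgetConfig",
    "budgeted_predict",
    "dynamic_predict",
    "select_budget_exit",
    "select_from_accuracies",
]


@dataclass(frozen=True)
class BudgetConfig:
    """Fixed exit layer m* used for all queries."""

    exit_layer: int

    def __post_init__(self) -> None:
        if self.exit_layer < 1:
            raise ConfigurationError("exit_layer must be >= 1")


def budgeted_predict(model: MultiExitTransformer, sample, budget: BudgetConfig) -> int:
    """Class prediction of the m*-th exit; layers beyond m* never run."""
    if budget.exit_layer > model.cfg.num_layers:
        raise ConfigurationError(
            f"exit layer {budget.exit_layer} exceeds model depth {model.cfg.num_layers}"
        )
    probs = model.forward_budgeted(sample, budget.exit_layer)
    return int(np.argmax(probs))


def dynamic_predict(
    model: MultiExitTransformer, sample, policy: PolicyConfig
) -> tuple[int, ExitTrace]:
    """Policy-driven per-instance inference (batch size 1)."""
    return model.forward_until_exit(sample, policy)


def select_from_accuracies(accuracies) -> int:
    """Smallest exit layer (1-based) maximizing dev accuracy."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size == 0:
        raise DataError("no per-layer accuracies provided")
    return int(np.argmax(acc)) + 1  # argmax returns the first maximum


def select_budget_exit(model: MultiExitTransformer, dev_set) -> BudgetConfig:
    """Pick m* by per-layer accuracy on a labelled dev set.

    Evaluates every exit over the dev set and returns the smallest layer
    attaining the maximum accuracy (cheapest among the best).
    """
    tokens, labels = _unpack(dev_set)
    if tokens.shape[0] == 0:
        raise DataError("dev set is empty")
    probs = model.forward_all_exits_batch(tokens)  # (N, M, K)
    preds = probs.argmax(axis=2)  # (N, M)
    accs = (preds == np.asarray(labels)[:, None]).mean(axis=0)
    return BudgetConfig(exit_layer=select_from_accuracies(accs))


def _unpack(data):
    if hasattr(data, "tokens") and hasattr(data, "labels"):
        return np.asarray(data.tokens), np.asarray(data.labels)
    tokens, labels = data
    return np.asarray(tokens), np.asarray(labels)
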