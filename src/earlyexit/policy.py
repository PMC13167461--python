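"""Backbone-free exit policies for multi-exit classifiers.

Three exit criteria operate on a per-layer sequence of class-probability
vectors ``p_1 .. p_M`` produced by intermediate classifier heads:

* **entropy**: exit at the first layer whose normalized prediction entropy
  ``H_m`` falls strictly below a threshold ``tau``;
* **patience**: exit once ``P_t`` consecutive layers agree on the argmax
  class (the patience counter ``P_m`` is the current run length of
  identical predictions, reset to 1 on disagreement);
* **epee**: the hybrid — exit at the first layer where *either* criterion
  holds.  Setting ``tau = 0`` disables the entropy test (the inequality is
  strict), recovering the patience-only policy; setting ``P_t = M``
  recovers the entropy-only policy because the counter cannot reach ``M``
  before the final layer, where exit is unconditional anyway.

The final layer always emits a prediction irrespective of confidence.

All functions here are pure and model-agnostic: a trajectory is any
``(M, K)`` array of probability vectors, however produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .exceptions import (
    ConfigurationError,
    InvalidClassSpaceError,
    InvalidDistributionError,
    InvalidLayerError,
    InvalidTrajectoryError,
)

__all__ = [
    "PolicyConfig",
    "PatienceState",
    "ExitTrace",
    "normalized_entropy",
    "argmax_class",
    "update_patience",
    "decide",
    "run_policy",
    "exit_layer_oracle",
]

#: tolerance for "entries sum to 1" validation; softmax outputs in double
#: precision are exact to ~1e-15, hand-typed vectors to much less.
_PROB_ATOL = 1e-6

Mode = Literal["entropy", "patience", "epee"]
Trigger = Literal["entropy", "patience", "both", "final_layer"]


@dataclass(frozen=True)
class PolicyConfig:
    """Exit-policy hyper-parameters.

    Parameters
    ----------
    mode:
        ``"epee"`` uses both criteria; ``"entropy"`` and ``"patience"``
        are the degenerate single-criterion policies, implemented exactly
        as epee with ``patience_threshold = M`` and ``tau = 0``
        respectively.
    tau:
        Entropy threshold in [0, 1]; exit fires when ``H_m < tau``
        (strict, so 0 disables the criterion).
    patience_threshold:
        Required run length ``P_t`` of agreeing predictions, in [1, M].
    """

    mode: Mode = "epee"
    tau: float = 0.0
    patience_threshold: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("entropy", "patience", "epee"):
            raise ConfigurationError(f"unknown policy mode {self.mode!r}")
        if not 0.0 <= self.tau <= 1.0:
            raise ConfigurationError(f"tau must lie in [0, 1], got {self.tau}")
        if self.patience_threshold < 1:
            raise ConfigurationError(
                f"patience_threshold must be >= 1, got {self.patience_threshold}"
            )

    def effective(self, num_layers: int) -> "PolicyConfig":
        """Resolve the mode into equivalent epee parameters for M layers."""
        if self.patience_threshold > num_layers:
            raise ConfigurationError(
                f"patience_threshold {self.patience_threshold} exceeds M={num_layers}"
            )
        if self.mode == "entropy":
            return replace(self, mode="epee", patience_threshold=num_layers)
        if self.mode == "patience":
            return replace(self, mode="epee", tau=0.0)
        return self


@dataclass(frozen=True)
class PatienceState:
    """Run length of consecutive agreeing argmax predictions.

    ``last_class is None`` denotes the pre-first-layer state; the first
    observation starts a run of length 1.
    """

    count: int = 0
    last_class: Optional[int] = None


@dataclass
class ExitTrace:
    """Per-sample record of one policy run, truncated at the exit layer."""

    exit_layer: int
    predicted_class: int
    trigger: Trigger
    entropies: list[float] = field(default_factory=list)
    patience_counts: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "exit_layer": self.exit_layer,
            "predicted_class": self.predicted_class,
            "trigger": self.trigger,
            "entropies": list(self.entropies),
            "patience_counts": list(self.patience_counts),
        }


def _validate_probs(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidDistributionError("probability vector must be 1-D and non-empty")
    if arr.size < 2:
        raise InvalidClassSpaceError("class space must contain at least 2 classes")
    if np.any(arr < -_PROB_ATOL) or np.any(arr > 1 + _PROB_ATOL):
        raise InvalidDistributionError("probabilities must lie in [0, 1]")
    if abs(arr.sum() - 1.0) > _PROB_ATOL:
        raise InvalidDistributionError(
            f"probabilities sum to {arr.sum():.6g}, expected 1"
        )
    return arr


def normalized_entropy(p: Sequence[float]) -> float:
    """Shannon entropy of ``p`` divided by ``log K``; in [0, 1].

    The normalization makes the value base-invariant: 0 for a one-hot
    (fully confident) prediction, 1 for the uniform distribution.  The
    convention ``0 * log 0 = 0`` applies.
    """
    arr = _validate_probs(p)
    pos = arr[arr > 0.0]
    h = -float(np.sum(pos * np.log(pos)))
    return h / np.log(arr.size)


def argmax_class(p: Sequence[float]) -> int:
    """Most probable class; ties broken deterministically to the lowest index."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidDistributionError("probability vector must be 1-D and non-empty")
    return int(np.argmax(arr))


def update_patience(state: PatienceState, current_class: int) -> PatienceState:
    """Advance the patience counter with this layer's predicted class.

    The counter increments when the prediction matches the previous
    layer's, and resets to 1 otherwise; the first observation is a run of
    length 1.
    """
    if current_class < 0:
        raise InvalidDistributionError(f"invalid class index {current_class}")
    if state.last_class is not None and current_class == state.last_class:
        return PatienceState(count=state.count + 1, last_class=current_class)
    return PatienceState(count=1, last_class=current_class)


def decide(
    entropy: float,
    patience_count: int,
    layer: int,
    cfg: PolicyConfig,
    num_layers: int,
) -> bool:
    """Exit decision at one layer; ``True`` means exit.

    Exit fires iff ``entropy < tau`` (strict) or ``patience_count >= P_t``
    or ``layer == M`` — the final layer always emits a prediction.
    """
    if not 1 <= layer <= num_layers:
        raise InvalidLayerError(f"layer {layer} outside [1, {num_layers}]")
    eff = cfg.effective(num_layers)
    return (
        entropy < eff.tau
        or patience_count >= eff.patience_threshold
        or layer == num_layers
    )


def _as_trajectory(trajectory) -> np.ndarray:
    arr = np.asarray(trajectory, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise InvalidTrajectoryError("trajectory must be a non-empty (M, K) array")
    return arr


def run_policy(trajectory, cfg: PolicyConfig) -> ExitTrace:
    """Scan layers 1..M in order and stop at the first exit decision.

    At each layer the normalized entropy is computed, the patience counter
    is advanced with the layer's argmax, and the exit test is applied.
    The returned trace is truncated at the exit layer; the prediction is
    the argmax of the exit layer's distribution.
    """
    traj = _as_trajectory(trajectory)
    num_layers = traj.shape[0]
    eff = cfg.effective(num_layers)

    state = PatienceState()
    entropies: list[float] = []
    counts: list[int] = []
    for m in range(1, num_layers + 1):
        p = traj[m - 1]
        h = normalized_entropy(p)
        cls = argmax_class(p)
        state = update_patience(state, cls)
        entropies.append(h)
        counts.append(state.count)
        if decide(h, state.count, m, eff, num_layers):
            ent_fired = h < eff.tau
            pat_fired = state.count >= eff.patience_threshold
            if ent_fired and pat_fired:
                trigger: Trigger = "both"
            elif ent_fired:
                trigger = "entropy"
            elif pat_fired:
                trigger = "patience"
            else:
                trigger = "final_layer"
            return ExitTrace(
                exit_layer=m,
                predicted_class=cls,
                trigger=trigger,
                entropies=entropies,
                patience_counts=counts,
            )
    raise AssertionError("unreachable: final layer always exits")


def exit_layer_oracle(trajectory, cfg: PolicyConfig) -> int:
    """Brute-force reference for ``run_policy``'s exit layer.

    Recomputes, independently for every candidate layer m, the entropy
    test and the terminal run length of identical argmax predictions
    ending at m (scanning backwards from scratch), and returns the first
    layer where either criterion holds, else M.  Shares no state with
    :func:`run_policy`; used to cross-validate it.
    """
    traj = _as_trajectory(trajectory)
    num_layers = traj.shape[0]
    eff = cfg.effective(num_layers)
    argmaxes = [argmax_class(traj[m]) for m in range(num_layers)]
    for m in range(1, num_layers + 1):
        if normalized_entropy(traj[m - 1]) < eff.tau:
            return m
        run = 1
        j = m - 1
        while j >= 1 and argmaxes[j] == argmaxes[j - 1]:
            run += 1
            j -= 1
        if run >= eff.patience_threshold:
            return m
    return num_layers
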