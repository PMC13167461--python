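"""Accuracy / speed-up evaluation for exit policies.

The efficiency of an early-exit strategy over a test set of N samples is
the layer-count speed-up ratio

    Speedup = 1 - (sum_i m_i) / (N * M),

where m_i is the exit layer of sample i: 0 means full-depth inference for
every sample, and the maximum 1 - 1/M means everything exits at layer 1.
The ratio is linear in computational cost and correlates strongly with
wall-clock latency, which this package deliberately does not measure.

Besides single-policy evaluation this module provides per-layer profiling
(accuracy and mean normalized entropy of each exit head), the
(tau, patience) grid surface used to map the accuracy/efficiency
trade-off, and an exact degeneracy check that the hybrid policy collapses
to its entropy-only and patience-only special cases.

Policy evaluation is trajectory-based: per-layer distributions are computed
once per sample (either supplied directly or via one batched model pass)
and every grid cell reuses the cached per-layer entropies and argmaxes.
The cached scan is the same decision procedure as
:func:`earlyexit.policy.run_policy`, just without recomputing entropies per
cell; tests assert the two paths agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .model import MultiExitTransformer
from .policy import PolicyConfig, run_policy

__all__ = [
    "EvalResult",
    "GridResult",
    "speedup_ratio",
    "evaluate_policy",
    "per_layer_profile",
    "grid_search",
    "degeneracy_check",
    "trajectory_stats",
    "plot_grid",
]


@dataclass
class EvalResult:
    """Accuracy, speed-up and exit-layer distribution for one policy."""

    accuracy: float
    speedup: float
    mean_exit_layer: float
    exit_histogram: np.ndarray  # counts per layer, length M

    @property
    def num_samples(self) -> int:
        return int(self.exit_histogram.sum())


@dataclass
class GridResult:
    """EvalResults over the (tau, patience) grid; rows tau, columns P_t."""

    taus: list[float]
    patiences: list[int]
    cells: dict[tuple[float, int], EvalResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tau in self.taus:
            for pt in self.patiences:
                r = self.cells[(tau, pt)]
                rows.append(
                    {
                        "tau": tau,
                        "patience": pt,
                        "accuracy": r.accuracy,
                        "speedup": r.speedup,
                        "mean_exit_layer": r.mean_exit_layer,
                    }
                )
        return pd.DataFrame(rows)


def speedup_ratio(exit_layers: Sequence[int], num_layers: int) -> float:
    """1 - (total layers executed) / (N * M); in [0, 1 - 1/M]."""
    layers = np.asarray(exit_layers)
    if layers.size == 0:
        raise DataError("no exit layers provided")
    if layers.min() < 1 or layers.max() > num_layers:
        raise ConfigurationError("exit layer outside [1, M]")
    return 1.0 - float(layers.sum()) / (layers.size * num_layers)


def trajectory_stats(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-layer normalized entropies and argmaxes for (N, M, K) trajectories."""
    if probs.ndim != 3:
        raise ConfigurationError("expected (N, M, K) trajectory array")
    K = probs.shape[2]
    safe = np.where(probs > 0.0, probs, 1.0)  # 0 log 0 = 0
    entropies = -(probs * np.log(safe)).sum(axis=2) / np.log(K)
    argmaxes = probs.argmax(axis=2)
    return entropies, argmaxes


def _exit_layers_from_stats(
    entropies: np.ndarray, argmaxes: np.ndarray, tau: float, patience_threshold: int
) -> np.ndarray:
    """Exit layer per sample from cached per-layer stats (same rule as
    run_policy: strict entropy test, patience updated before the test)."""
    N, M = entropies.shape
    out = np.empty(N, dtype=np.int64)
    for i in range(N):
        count = 0
        last = -1
        for m in range(M):
            cls = argmaxes[i, m]
            count = count + 1 if cls == last else 1
            last = cls
            if entropies[i, m] < tau or count >= patience_threshold or m == M - 1:
                out[i] = m + 1
                break
    return out


def evaluate_policy(
    trajectories: np.ndarray, labels: np.ndarray, policy: PolicyConfig
) -> EvalResult:
    """Accuracy / speed-up of one policy over (N, M, K) trajectories."""
    probs = np.asarray(trajectories, dtype=float)
    labels = np.asarray(labels)
    if probs.shape[0] == 0:
        raise DataError("no trajectories provided")
    M = probs.shape[1]
    eff = policy.effective(M)
    entropies, argmaxes = trajectory_stats(probs)
    exits = _exit_layers_from_stats(entropies, argmaxes, eff.tau, eff.patience_threshold)
    preds = argmaxes[np.arange(len(exits)), exits - 1]
    hist = np.bincount(exits, minlength=M + 1)[1:]
    return EvalResult(
        accuracy=float((preds == labels).mean()),
        speedup=speedup_ratio(exits, M),
        mean_exit_layer=float(exits.mean()),
        exit_histogram=hist,
    )


def _trajectories_of(model_or_trajs, data=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept (model, corpus) or a TrajectorySet-like object."""
    if isinstance(model_or_trajs, MultiExitTransformer):
        if data is None:
            raise DataError("labelled data required alongside a model")
        tokens = np.asarray(data.tokens if hasattr(data, "tokens") else data[0])
        labels = np.asarray(data.labels if hasattr(data, "labels") else data[1])
        if tokens.shape[0] == 0:
            raise DataError("empty evaluation set")
        return model_or_trajs.forward_all_exits_batch(tokens), labels
    ts = model_or_trajs
    return np.asarray(ts.probs), np.asarray(ts.labels)


def per_layer_profile(model_or_trajs, data=None) -> pd.DataFrame:
    """Accuracy and mean normalized entropy of every exit head.

    Accepts a trained model plus a labelled corpus, or a precomputed
    trajectory set.  Returns one row per layer.
    """
    probs, labels = _trajectories_of(model_or_trajs, data)
    entropies, argmaxes = trajectory_stats(probs)
    acc = (argmaxes == labels[:, None]).mean(axis=0)
    return pd.DataFrame(
        {
            "layer": np.arange(1, probs.shape[1] + 1),
            "accuracy": acc,
            "mean_entropy": entropies.mean(axis=0),
        }
    )


def grid_search(
    model_or_trajs,
    data=None,
    taus: Sequence[float] = (0.0, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0),
    patiences: Optional[Sequence[int]] = None,
) -> GridResult:
    """Dynamic-mode accuracy/speed-up surface over (tau, P_t) pairs.

    The tau = 0 row reproduces the patience-only policy and the P_t = M
    column the entropy-only policy, cell for cell.  Trajectories are
    computed once and shared across all cells.
    """
    probs, labels = _trajectories_of(model_or_trajs, data)
    M = probs.shape[1]
    if patiences is None:
        patiences = list(range(1, M + 1))
    taus = list(taus)
    patiences = [int(p) for p in patiences]
    if not taus or not patiences:
        raise ConfigurationError("tau and patience lists must be non-empty")
    if any(not 0 <= t <= 1 for t in taus):
        raise ConfigurationError("tau values must lie in [0, 1]")
    if any(not 1 <= p <= M for p in patiences):
        raise ConfigurationError("patience values must lie in [1, M]")

    result = GridResult(taus=taus, patiences=patiences)
    for tau in taus:
        for pt in patiences:
            cfg = PolicyConfig(mode="epee", tau=tau, patience_threshold=pt)
            result.cells[(tau, pt)] = evaluate_policy(probs, labels, cfg)
    return result


def degeneracy_check(
    model_or_trajs, data=None, tau: float = 0.3, patience: int = 3
) -> tuple[bool, bool]:
    """Exact trace-level degeneracy of the hybrid policy.

    Returns ``(patience_ok, entropy_ok)``: whether hybrid traces with
    tau = 0 equal patience-only traces for every sample, and whether hybrid
    traces with P_t = M equal entropy-only traces.  Comparison covers exit
    layer, prediction, entropies and patience counts.
    """
    probs, _ = _trajectories_of(model_or_trajs, data)
    M = probs.shape[1]
    patience_ok = True
    entropy_ok = True
    for traj in probs:
        a = run_policy(traj, PolicyConfig("epee", tau=0.0, patience_threshold=patience))
        b = run_policy(traj, PolicyConfig("patience", patience_threshold=patience))
        if a.to_dict() != b.to_dict():
            patience_ok = False
        c = run_policy(traj, PolicyConfig("epee", tau=tau, patience_threshold=M))
        d = run_policy(traj, PolicyConfig("entropy", tau=tau, patience_threshold=1))
        if c.to_dict() != d.to_dict():
            entropy_ok = False
    return patience_ok, entropy_ok


def plot_grid(grid: GridResult, metric: str = "speedup", path=None):
    """Heat-map of one grid metric (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = grid.to_frame().pivot(index="tau", columns="patience", values=metric)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(frame.values, aspect="auto", origin="lower", cmap="viridis")
    ax.set_xticks(range(len(frame.columns)), frame.columns)
    ax.set_yticks(range(len(frame.index)), frame.index)
    ax.set_xlabel("patience threshold $P_t$")
    ax.set_ylabel(r"entropy threshold $\tau$")
    ax.set_title(metric)
    fig.colorbar(im, ax=ax)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
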