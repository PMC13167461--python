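"""Seeded synthetic data: labelled token corpora and per-layer trajectories.

Two generators make every other module testable without any external
dataset.

**Corpora** (:func:`generate_corpus`) are class-balanced token sequences
with a controllable easy/hard difficulty mixture.  A fixed pool of one
"evidence" token per class carries the label signal: easy records place
several evidence tokens of the true class in the earliest content
positions, while hard records hide a single evidence token at a random
position among filler drawn from the non-evidence vocabulary.  An easy
record's label is therefore recoverable by a trivial bag-of-evidence-tokens
rule, which doubles as a by-construction oracle in tests.  Position 0 is a
reserved classification token (id 0) so first-token pooling has a stable
read-out slot.

**Trajectories** (:func:`generate_trajectories`) are model-free stand-ins
for per-layer exit-head outputs: at layer m the distribution is the softmax
of a logit vector whose true-class margin grows linearly with m
(``convergence_rate``) plus zero-mean Gaussian noise.  Expected normalized
entropy therefore declines with depth — the qualitative signature of
trained multi-exit classifiers, whose deeper heads grow more confident —
while low rates and high noise produce the oscillating-prediction regime
that exercises patience-based exits.  ``label_flip_rate`` injects
irreducible label error so accuracy ceilings below 1 are testable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterator

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "CorpusSpec",
    "Corpus",
    "TrajectorySpec",
    "TrajectorySet",
    "generate_corpus",
    "generate_trajectories",
    "evidence_rule_predict",
    "CLS_TOKEN",
]

#: reserved classification token at position 0 of every record
CLS_TOKEN = 0


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for the synthetic classification corpus."""

    num_samples: int = 2000
    num_classes: int = 4
    sequence_length: int = 16
    vocab_size: int = 30
    easy_fraction: float = 0.5
    evidence_strength: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_samples < 1 or self.num_classes < 2:
            raise ConfigurationError("need num_samples >= 1 and num_classes >= 2")
        if self.sequence_length < 3:
            raise ConfigurationError("sequence_length must be >= 3")
        if not 0.0 <= self.easy_fraction <= 1.0:
            raise ConfigurationError("easy_fraction must lie in [0, 1]")
        if self.evidence_strength <= 0:
            raise ConfigurationError("evidence_strength must be positive")
        # ids: CLS, one evidence token per class, at least one filler token
        if self.vocab_size < self.num_classes + 2:
            raise ConfigurationError(
                f"vocab_size {self.vocab_size} too small for {self.num_classes} "
                "evidence tokens plus CLS and filler"
            )


@dataclass
class Corpus:
    """In-memory labelled corpus: (N, T) token ids, (N,) labels."""

    tokens: np.ndarray
    labels: np.ndarray
    difficulty: np.ndarray  # array of "easy"/"hard" strings
    spec: CorpusSpec

    def __len__(self) -> int:
        return self.tokens.shape[0]

    def subset(self, idx) -> "Corpus":
        return Corpus(self.tokens[idx], self.labels[idx], self.difficulty[idx], self.spec)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for tok, lab, diff in zip(self.tokens, self.labels, self.difficulty):
                fh.write(
                    json.dumps(
                        {"tokens": tok.tolist(), "label": int(lab), "difficulty": str(diff)}
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path, spec: CorpusSpec | None = None) -> "Corpus":
        toks, labs, diffs = [], [], []
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                toks.append(rec["tokens"])
                labs.append(rec["label"])
                diffs.append(rec.get("difficulty", "easy"))
        return cls(
            np.asarray(toks, dtype=np.int64),
            np.asarray(labs, dtype=np.int64),
            np.asarray(diffs),
            spec or CorpusSpec(num_samples=len(labs)),
        )


def _evidence_token(class_index: int) -> int:
    return class_index + 1  # ids 1..K are evidence tokens


def evidence_rule_predict(tokens: np.ndarray, num_classes: int) -> int:
    """Bag-of-evidence-tokens decision rule: most frequent evidence token's
    class, ties to the lowest class index, class 0 if no evidence present."""
    counts = [int(np.sum(tokens == _evidence_token(k))) for k in range(num_classes)]
    return int(np.argmax(counts))


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Deterministic class-balanced corpus with an easy/hard mixture.

    Labels are balanced within +/-1 per class.  The easy/hard tag of each
    record and the evidence placement are drawn from a generator seeded by
    ``spec.seed``, so identical specs reproduce identical corpora.
    """
    rng = np.random.default_rng(spec.seed)
    N, K, T = spec.num_samples, spec.num_classes, spec.sequence_length
    filler_lo, filler_hi = K + 1, spec.vocab_size  # filler ids exclude evidence
    n_easy = int(round(spec.easy_fraction * N))
    n_evidence = max(1, int(round(spec.evidence_strength)))
    if n_evidence > T - 1:
        raise ConfigurationError("evidence_strength exceeds available positions")

    labels = np.arange(N) % K  # balanced within +/-1
    easy = np.zeros(N, dtype=bool)
    easy[:n_easy] = True
    perm = rng.permutation(N)
    labels, easy = labels[perm], easy[perm]

    tokens = rng.integers(filler_lo, filler_hi, size=(N, T))
    tokens[:, 0] = CLS_TOKEN
    for i in range(N):
        ev = _evidence_token(int(labels[i]))
        if easy[i]:
            tokens[i, 1 : 1 + n_evidence] = ev
        else:
            pos = int(rng.integers(1, T))
            tokens[i, pos] = ev
    difficulty = np.where(easy, "easy", "hard")
    return Corpus(tokens.astype(np.int64), labels.astype(np.int64), difficulty, spec)


@dataclass(frozen=True)
class TrajectorySpec:
    """Study conditions for model-free per-layer probability trajectories."""

    num_samples: int = 1000
    num_layers: int = 12
    num_classes: int = 4
    convergence_rate: float = 0.35
    noise_scale: float = 0.75
    label_flip_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_samples < 1 or self.num_layers < 1 or self.num_classes < 2:
            raise ConfigurationError("invalid trajectory geometry")
        if self.convergence_rate < 0 or self.noise_scale < 0:
            raise ConfigurationError("convergence_rate and noise_scale must be >= 0")
        if not 0.0 <= self.label_flip_rate <= 1.0:
            raise ConfigurationError("label_flip_rate must lie in [0, 1]")


@dataclass
class TrajectorySet:
    """(N, M, K) per-layer distributions with (N,) labels."""

    probs: np.ndarray
    labels: np.ndarray
    spec: TrajectorySpec

    def __len__(self) -> int:
        return self.probs.shape[0]

    def __iter__(self) -> Iterator[tuple[np.ndarray, int]]:
        for i in range(len(self)):
            yield self.probs[i], int(self.labels[i])

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for traj, lab in self:
                fh.write(json.dumps({"probs": traj.tolist(), "label": lab}) + "\n")

    @classmethod
    def from_jsonl(cls, path, spec: TrajectorySpec | None = None) -> "TrajectorySet":
        probs, labs = [], []
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                probs.append(rec["probs"])
                labs.append(rec["label"])
        arr = np.asarray(probs, dtype=float)
        return cls(
            arr,
            np.asarray(labs, dtype=np.int64),
            spec
            or TrajectorySpec(
                num_samples=arr.shape[0], num_layers=arr.shape[1], num_classes=arr.shape[2]
            ),
        )


def generate_trajectories(spec: TrajectorySpec) -> TrajectorySet:
    """Per-layer probability trajectories with depth-decreasing entropy.

    Layer-m logits are i.i.d. N(0, noise_scale^2) for every class plus a
    deterministic margin ``convergence_rate * m`` on the sample's true
    class; distributions are the softmax of those logits.  With the flip
    rate q, a fraction q of labels is reassigned uniformly to a different
    class while the trajectory keeps pointing at the original class.
    """
    rng = np.random.default_rng(spec.seed)
    N, M, K = spec.num_samples, spec.num_layers, spec.num_classes
    true = rng.integers(0, K, size=N)
    logits = rng.normal(0.0, spec.noise_scale, size=(N, M, K)) if spec.noise_scale > 0 \
        else np.zeros((N, M, K))
    depth = spec.convergence_rate * np.arange(1, M + 1)
    logits[np.arange(N)[:, None], np.arange(M)[None, :], true[:, None]] += depth[None, :]
    z = logits - logits.max(axis=2, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=2, keepdims=True)

    labels = true.copy()
    flip = rng.random(N) < spec.label_flip_rate
    if flip.any() and K > 1:
        offsets = rng.integers(1, K, size=int(flip.sum()))
        labels[flip] = (labels[flip] + offsets) % K
    return TrajectorySet(probs, labels.astype(np.int64), spec)
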