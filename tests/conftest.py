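import numpy as np
import pytest

import earlyexit as ee


@pytest.fixture(scope="session")
def trained_setup():
    """A tiny multi-exit transformer trained on a small synthetic corpus.

    Shared across model-dependent tests; returns (model, train_corpus,
    test_corpus).  Trained once per session to keep the suite fast.
    """
    corpus = ee.generate_corpus(
        ee.CorpusSpec(num_samples=600, num_classes=4, seed=7)
    )
    train_c = corpus.subset(slice(0, 400))
    test_c = corpus.subset(slice(400, None))
    model = ee.build_model(ee.TINY, seed=7)
    ee.train(model, train_c, ee.TrainConfig(seed=7, epochs=6))
    return model, train_c, test_c


@pytest.fixture(scope="session")
def untrained_model():
    return ee.build_model(ee.TINY, seed=3)


def make_trajectory(entropies, argmaxes, num_classes=3):
    """Probability trajectory realizing given per-layer normalized entropies
    and argmax classes; inverts the entropy of a (p, rest uniform) vector
    by bisection."""
    from scipy.optimize import brentq

    def vec(h, cls):
        if h == 0.0:
            p = np.zeros(num_classes)
            p[cls] = 1.0
            return p

        def f(q):
            rest = (1.0 - q) / (num_classes - 1)
            s = q * np.log(q)
            if rest > 0:
                s += (num_classes - 1) * rest * np.log(rest)
            return -s / np.log(num_classes) - h

        q = brentq(f, 1.0 / num_classes + 1e-12, 1.0 - 1e-12)
        p = np.full(num_classes, (1.0 - q) / (num_classes - 1))
        p[cls] = q
        return p

    return np.array([vec(h, c) for h, c in zip(entropies, argmaxes)])


def random_trajectories(rng, n, max_layers=12, max_classes=9):
    """Heterogeneous random softmax trajectories for randomized policy tests."""
    out = []
    for _ in range(n):
        M = int(rng.integers(2, max_layers + 1))
        K = int(rng.integers(2, max_classes + 1))
        logits = rng.normal(0, rng.uniform(0.2, 2.5), size=(M, K))
        z = np.exp(logits - logits.max(axis=1, keepdims=True))
        out.append(z / z.sum(axis=1, keepdims=True))
    return out
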