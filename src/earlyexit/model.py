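"""Multi-exit transformer backbone with an affine classifier head per layer.

The backbone is a standard pre-norm transformer (token + learned position
embeddings, multi-head self-attention, GELU feed-forward, residual
connections) implemented directly on NumPy arrays with hand-written
backpropagation, so the whole package trains and runs on a single CPU with
no deep-learning framework.  After every layer ``m`` an affine exit head
maps the pooled hidden state ``s_m`` to logits over ``K`` classes;
``softmax`` of those logits is the per-layer distribution ``p_m`` consumed
by the exit policies.

Layer-wise execution is first-class: :meth:`MultiExitTransformer.forward_until_exit`
evaluates blocks strictly sequentially, applies the exit policy after each
one, and never touches a layer past the exit layer (an instrumented
per-block call counter makes this testable).

Exact parameter accounting is provided in closed form
(:func:`count_parameters`, :func:`exit_head_overhead`) and matches the
instantiated arrays; the published base encoder / decoder geometries are
available as presets for auditing against their known parameter totals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Literal, Optional

import numpy as np

from .exceptions import ConfigurationError, InputError
from .policy import (
    ExitTrace,
    PatienceState,
    PolicyConfig,
    argmax_class,
    decide,
    normalized_entropy,
    update_patience,
)

__all__ = [
    "MultiExitConfig",
    "MultiExitTransformer",
    "build_model",
    "count_parameters",
    "count_exit_head_parameters",
    "exit_head_overhead",
    "BASE_ENCODER",
    "BASE_DECODER",
    "TINY",
]

_LN_EPS = 1e-5
_INIT_STD = 0.02
_CHECKPOINT_VERSION = 1

Pooling = Literal["first_token", "last_token", "mean"]


@dataclass(frozen=True)
class MultiExitConfig:
    """Backbone + exit-head geometry.

    ``num_token_types``, ``embedding_layer_norm``, ``include_pooler`` and
    ``final_layer_norm`` cover the small architectural differences between
    encoder-style (segment embeddings, embedding LayerNorm, tanh pooler)
    and decoder-style (causal mask, final LayerNorm, tied output
    embedding, hence no extra output parameters) backbones, so parameter
    audits of both families use one closed form.
    """

    num_layers: int = 6
    hidden_size: int = 64
    num_heads: int = 4
    ffn_size: int = 128
    vocab_size: int = 50
    max_positions: int = 32
    num_token_types: int = 0
    num_classes: int = 4
    pooling: Pooling = "first_token"
    include_pooler: bool = False
    embedding_layer_norm: bool = True
    final_layer_norm: bool = False
    causal: bool = False

    def __post_init__(self) -> None:
        if self.num_layers < 1 or self.hidden_size < 1 or self.ffn_size < 1:
            raise ConfigurationError("num_layers, hidden_size, ffn_size must be >= 1")
        if self.num_heads < 1 or self.hidden_size % self.num_heads != 0:
            raise ConfigurationError(
                f"num_heads ({self.num_heads}) must divide hidden_size "
                f"({self.hidden_size})"
            )
        if self.vocab_size < 2 or self.num_classes < 2:
            raise ConfigurationError("vocab_size and num_classes must be >= 2")
        if self.max_positions < 1 or self.num_token_types < 0:
            raise ConfigurationError("invalid position/token-type geometry")
        if self.pooling not in ("first_token", "last_token", "mean"):
            raise ConfigurationError(f"unknown pooling {self.pooling!r}")


#: Published base encoder geometry (109M-parameter class).
BASE_ENCODER = MultiExitConfig(
    num_layers=12,
    hidden_size=768,
    num_heads=12,
    ffn_size=3072,
    vocab_size=30522,
    max_positions=512,
    num_token_types=2,
    num_classes=2,
    pooling="first_token",
    include_pooler=True,
    embedding_layer_norm=True,
    final_layer_norm=False,
    causal=False,
)

#: Published base decoder geometry (124M-parameter class, tied output embedding).
BASE_DECODER = MultiExitConfig(
    num_layers=12,
    hidden_size=768,
    num_heads=12,
    ffn_size=3072,
    vocab_size=50257,
    max_positions=1024,
    num_token_types=0,
    num_classes=2,
    pooling="last_token",
    include_pooler=False,
    embedding_layer_norm=False,
    final_layer_norm=True,
    causal=True,
)

#: Desk-scale default: trains from scratch on one CPU in seconds.
TINY = MultiExitConfig()


def count_parameters(cfg: MultiExitConfig) -> int:
    """Exact trainable-parameter count of the backbone, excluding exit heads.

    Closed-form sum over embeddings, the per-layer attention / feed-forward
    / normalization weights, and the optional pooler and final LayerNorm.
    """
    d, f = cfg.hidden_size, cfg.ffn_size
    emb = (cfg.vocab_size + cfg.max_positions + cfg.num_token_types) * d
    if cfg.embedding_layer_norm:
        emb += 2 * d
    per_layer = (
        4 * (d * d + d)  # Q, K, V, output projections with biases
        + (d * f + f) + (f * d + d)  # feed-forward up / down
        + 2 * (2 * d)  # two LayerNorms
    )
    total = emb + cfg.num_layers * per_layer
    if cfg.final_layer_norm:
        total += 2 * d
    if cfg.include_pooler:
        total += d * d + d
    return total


def count_exit_head_parameters(cfg: MultiExitConfig) -> int:
    """Parameters added by one affine head per layer: M * (d*K + K)."""
    return cfg.num_layers * (cfg.hidden_size * cfg.num_classes + cfg.num_classes)


def exit_head_overhead(cfg: MultiExitConfig) -> float:
    """Exit heads' share of the full model, as a percentage.

    100 * M(dK + K) / (backbone + M(dK + K)).  For published base
    geometries this is well under one percent.
    """
    heads = count_exit_head_parameters(cfg)
    return 100.0 * heads / (count_parameters(cfg) + heads)


# ---------------------------------------------------------------------------
# layer primitives: forward returns (out, cache); backward consumes cache


def _layer_norm_forward(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _layer_norm_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


_GELU_C = np.sqrt(2.0 / np.pi)


def _gelu(x):
    return 0.5 * x * (1.0 + np.tanh(_GELU_C * (x + 0.044715 * x**3)))


def _gelu_grad(x):
    t = np.tanh(_GELU_C * (x + 0.044715 * x**3))
    dt = (1.0 - t**2) * _GELU_C * (1.0 + 3 * 0.044715 * x**2)
    return 0.5 * (1.0 + t) + 0.5 * x * dt


def _softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _attention_forward(a, p, num_heads, causal):
    """Multi-head self-attention on (B, T, d) input ``a`` (post-LayerNorm)."""
    B, T, d = a.shape
    dh = d // num_heads

    def split(x):  # (B, T, d) -> (B, h, T, dh)
        return x.reshape(B, T, num_heads, dh).transpose(0, 2, 1, 3)

    q = split(a @ p["Wq"] + p["bq"])
    k = split(a @ p["Wk"] + p["bk"])
    v = split(a @ p["Wv"] + p["bv"])
    scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh)
    if causal:
        mask = np.triu(np.full((T, T), -np.inf), k=1)
        scores = scores + mask
    attn = _softmax(scores)
    ctx = attn @ v  # (B, h, T, dh)
    ctx_m = ctx.transpose(0, 2, 1, 3).reshape(B, T, d)
    out = ctx_m @ p["Wo"] + p["bo"]
    return out, (a, q, k, v, attn, ctx_m)


def _attention_backward(dout, cache, p, num_heads):
    a, q, k, v, attn, ctx_m = cache
    B, T, d = a.shape
    dh = d // num_heads

    def split(x):
        return x.reshape(B, T, num_heads, dh).transpose(0, 2, 1, 3)

    def merge(x):  # (B, h, T, dh) -> (B, T, d)
        return x.transpose(0, 2, 1, 3).reshape(B, T, d)

    grads = {}
    grads["Wo"] = ctx_m.reshape(-1, d).T @ dout.reshape(-1, d)
    grads["bo"] = dout.sum(axis=(0, 1))
    dctx = split(dout @ p["Wo"].T)

    dattn = dctx @ v.transpose(0, 1, 3, 2)
    dv = attn.transpose(0, 1, 3, 2) @ dctx
    # softmax backward (masked entries have attn == 0, so they drop out)
    dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
    dscores /= np.sqrt(dh)
    dq = dscores @ k
    dk = dscores.transpose(0, 1, 3, 2) @ q

    da = np.zeros_like(a)
    for name, dproj in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
        dflat = merge(dproj).reshape(-1, d)
        grads[name] = a.reshape(-1, d).T @ dflat
        grads["b" + name[1:]] = dflat.sum(axis=0)
        da += dflat.reshape(B, T, d) @ p[name].T
    return da, grads


def _block_forward(x, p, num_heads, causal):
    """Pre-norm transformer block: x + Attn(LN1(x)), then + FFN(LN2(.))."""
    a, ln1_cache = _layer_norm_forward(x, p["ln1_g"], p["ln1_b"])
    attn_out, attn_cache = _attention_forward(a, p, num_heads, causal)
    x1 = x + attn_out
    b, ln2_cache = _layer_norm_forward(x1, p["ln2_g"], p["ln2_b"])
    h1 = b @ p["W1"] + p["b1"]
    r = _gelu(h1)
    y = x1 + (r @ p["W2"] + p["b2"])
    return y, (ln1_cache, attn_cache, ln2_cache, b, h1, r)


def _block_backward(dy, cache, p, num_heads):
    ln1_cache, attn_cache, ln2_cache, b, h1, r = cache
    d = b.shape[-1]
    grads = {}
    # feed-forward branch
    grads["W2"] = r.reshape(-1, r.shape[-1]).T @ dy.reshape(-1, d)
    grads["b2"] = dy.sum(axis=(0, 1))
    dr = dy @ p["W2"].T
    dh1 = dr * _gelu_grad(h1)
    grads["W1"] = b.reshape(-1, d).T @ dh1.reshape(-1, dh1.shape[-1])
    grads["b1"] = dh1.sum(axis=(0, 1))
    db = dh1 @ p["W1"].T
    dx1_ffn, grads["ln2_g"], grads["ln2_b"] = _layer_norm_backward(db, ln2_cache)
    dx1 = dy + dx1_ffn
    # attention branch
    da, attn_grads = _attention_backward(dx1, attn_cache, p, num_heads)
    grads.update(attn_grads)
    dx_ln1, grads["ln1_g"], grads["ln1_b"] = _layer_norm_backward(da, ln1_cache)
    dx = dx1 + dx_ln1
    return dx, grads


class MultiExitTransformer:
    """Trainable multi-exit transformer; all arrays are float64 NumPy.

    Parameters are held in ``self.params`` (embeddings, per-block weights,
    optional pooler / final LayerNorm) and ``self.heads`` (one affine map
    per layer).  ``self.layer_calls`` counts transformer-block executions
    since the last :meth:`reset_layer_calls`, which is how tests assert
    that early exits really truncate computation.
    """

    def __init__(self, cfg: MultiExitConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        d, f = cfg.hidden_size, cfg.ffn_size

        def w(*shape):
            return rng.normal(0.0, _INIT_STD, size=shape)

        p: dict[str, np.ndarray] = {
            "tok_emb": w(cfg.vocab_size, d),
            "pos_emb": w(cfg.max_positions, d),
        }
        if cfg.num_token_types:
            p["type_emb"] = w(cfg.num_token_types, d)
        if cfg.embedding_layer_norm:
            p["emb_ln_g"] = np.ones(d)
            p["emb_ln_b"] = np.zeros(d)
        for m in range(cfg.num_layers):
            pre = f"L{m}_"
            p[pre + "ln1_g"] = np.ones(d)
            p[pre + "ln1_b"] = np.zeros(d)
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[pre + name] = w(d, d)
                p[pre + "b" + name[1:]] = np.zeros(d)
            p[pre + "ln2_g"] = np.ones(d)
            p[pre + "ln2_b"] = np.zeros(d)
            p[pre + "W1"] = w(d, f)
            p[pre + "b1"] = np.zeros(f)
            p[pre + "W2"] = w(f, d)
            p[pre + "b2"] = np.zeros(d)
        if cfg.final_layer_norm:
            p["final_ln_g"] = np.ones(d)
            p["final_ln_b"] = np.zeros(d)
        if cfg.include_pooler:
            p["pooler_W"] = w(d, d)
            p["pooler_b"] = np.zeros(d)
        for m in range(cfg.num_layers):
            p[f"H{m}_W"] = w(d, cfg.num_classes)
            p[f"H{m}_b"] = np.zeros(cfg.num_classes)
        self.params = p
        self.layer_calls = 0

    # -- bookkeeping --------------------------------------------------------

    def reset_layer_calls(self) -> None:
        self.layer_calls = 0

    def num_backbone_parameters(self) -> int:
        return sum(v.size for k, v in self.params.items() if not k.startswith("H"))

    def num_head_parameters(self) -> int:
        return sum(v.size for k, v in self.params.items() if k.startswith("H"))

    def _block_params(self, m: int) -> dict:
        pre = f"L{m}_"
        return {k[len(pre):]: v for k, v in self.params.items() if k.startswith(pre)}

    # -- forward ------------------------------------------------------------

    def _validate_tokens(self, tokens: np.ndarray) -> np.ndarray:
        tok = np.asarray(tokens)
        if tok.ndim == 1:
            tok = tok[None, :]
        if tok.shape[1] > self.cfg.max_positions:
            raise InputError(
                f"sequence length {tok.shape[1]} exceeds max_positions "
                f"{self.cfg.max_positions}"
            )
        if tok.min() < 0 or tok.max() >= self.cfg.vocab_size:
            raise InputError("token id outside vocabulary")
        return tok.astype(np.int64)

    def _embed(self, tok: np.ndarray):
        p = self.params
        x = p["tok_emb"][tok] + p["pos_emb"][: tok.shape[1]][None, :, :]
        emb_cache = None
        if self.cfg.embedding_layer_norm:
            x, emb_cache = _layer_norm_forward(x, p["emb_ln_g"], p["emb_ln_b"])
        return x, emb_cache

    def _pool(self, x: np.ndarray) -> np.ndarray:
        if self.cfg.pooling == "first_token":
            return x[:, 0, :]
        if self.cfg.pooling == "last_token":
            return x[:, -1, :]
        return x.mean(axis=1)

    def _exit_logits(self, x: np.ndarray, m: int):
        """Pooled hidden state of block m (0-based) -> head logits."""
        p = self.params
        h = x
        if self.cfg.final_layer_norm:
            h, _ = _layer_norm_forward(h, p["final_ln_g"], p["final_ln_b"])
        pooled = self._pool(h)
        if self.cfg.include_pooler:
            pooled = np.tanh(pooled @ p["pooler_W"] + p["pooler_b"])
        return pooled @ p[f"H{m}_W"] + p[f"H{m}_b"]

    def forward_all_exits_batch(self, tokens) -> np.ndarray:
        """All per-layer distributions for a batch: (B, M, K)."""
        tok = self._validate_tokens(tokens)
        x, _ = self._embed(tok)
        probs = np.empty((tok.shape[0], self.cfg.num_layers, self.cfg.num_classes))
        for m in range(self.cfg.num_layers):
            x, _ = _block_forward(
                x, self._block_params(m), self.cfg.num_heads, self.cfg.causal
            )
            self.layer_calls += 1
            probs[:, m, :] = _softmax(self._exit_logits(x, m))
        return probs

    def forward_all_exits(self, sample) -> np.ndarray:
        """Per-layer trajectory p_1..p_M for one sample: (M, K)."""
        return self.forward_all_exits_batch(np.asarray(sample)[None, :])[0]

    def forward_budgeted(self, sample, exit_layer: int) -> np.ndarray:
        """Run exactly ``exit_layer`` blocks, return that head's distribution."""
        if not 1 <= exit_layer <= self.cfg.num_layers:
            raise ConfigurationError(
                f"exit layer {exit_layer} outside [1, {self.cfg.num_layers}]"
            )
        tok = self._validate_tokens(np.asarray(sample)[None, :])
        x, _ = self._embed(tok)
        for m in range(exit_layer):
            x, _ = _block_forward(
                x, self._block_params(m), self.cfg.num_heads, self.cfg.causal
            )
            self.layer_calls += 1
        return _softmax(self._exit_logits(x, exit_layer - 1))[0]

    def forward_until_exit(self, sample, policy: PolicyConfig):
        """Sequential per-layer evaluation under an exit policy.

        Returns ``(predicted_class, ExitTrace)``.  The hidden state is
        computed once per block and reused; no block past the exit layer
        runs.  Equivalent, trace-for-trace, to running
        :func:`earlyexit.policy.run_policy` on the full trajectory.
        """
        M = self.cfg.num_layers
        eff = policy.effective(M)
        tok = self._validate_tokens(np.asarray(sample)[None, :])
        x, _ = self._embed(tok)
        state = PatienceState()
        entropies: list[float] = []
        counts: list[int] = []
        for m in range(1, M + 1):
            x, _ = _block_forward(
                x, self._block_params(m - 1), self.cfg.num_heads, self.cfg.causal
            )
            self.layer_calls += 1
            p = _softmax(self._exit_logits(x, m - 1))[0]
            h = normalized_entropy(p)
            cls = argmax_class(p)
            state = update_patience(state, cls)
            entropies.append(h)
            counts.append(state.count)
            if decide(h, state.count, m, eff, M):
                ent = h < eff.tau
                pat = state.count >= eff.patience_threshold
                trigger = (
                    "both" if ent and pat
                    else "entropy" if ent
                    else "patience" if pat
                    else "final_layer"
                )
                trace = ExitTrace(
                    exit_layer=m,
                    predicted_class=cls,
                    trigger=trigger,
                    entropies=entropies,
                    patience_counts=counts,
                )
                return cls, trace
        raise AssertionError("unreachable: final layer always exits")

    # -- training forward/backward ------------------------------------------

    def joint_loss_and_grads(self, tokens, labels, weights: np.ndarray):
        """Layer-cost-weighted cross-entropy over a batch, with gradients.

        Loss is sum_m w_m * CE_m / sum_m w_m averaged over the batch, where
        CE_m is the cross-entropy of head m.  Returns ``(loss, grads,
        per_exit_correct)`` with ``grads`` keyed like ``self.params``.
        """
        cfg = self.cfg
        tok = self._validate_tokens(tokens)
        y = np.asarray(labels, dtype=np.int64)
        B = tok.shape[0]
        w = np.asarray(weights, dtype=float)
        wsum = w.sum()

        p = self.params
        x, emb_cache = self._embed(tok)
        xs = [x]
        block_caches = []
        for m in range(cfg.num_layers):
            x, cache = _block_forward(x, self._block_params(m), cfg.num_heads, cfg.causal)
            self.layer_calls += 1
            xs.append(x)
            block_caches.append(cache)

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        loss = 0.0
        per_exit_correct = np.zeros(cfg.num_layers, dtype=np.int64)
        head_dx = []  # gradient w.r.t. each block's output from its head
        onehot = np.eye(cfg.num_classes)[y]
        for m in range(cfg.num_layers):
            h = xs[m + 1]
            fln_cache = None
            if cfg.final_layer_norm:
                h, fln_cache = _layer_norm_forward(h, p["final_ln_g"], p["final_ln_b"])
            pooled = self._pool(h)
            pool_pre = None
            if cfg.include_pooler:
                pool_pre = pooled
                pooled = np.tanh(pooled @ p["pooler_W"] + p["pooler_b"])
            logits = pooled @ p[f"H{m}_W"] + p[f"H{m}_b"]
            probs = _softmax(logits)
            per_exit_correct[m] = int((probs.argmax(axis=1) == y).sum())
            ce = -np.log(np.maximum(probs[np.arange(B), y], 1e-12))
            loss += (w[m] / wsum) * ce.mean()

            dlogits = (probs - onehot) * (w[m] / (wsum * B))
            grads[f"H{m}_W"] += pooled.T @ dlogits
            grads[f"H{m}_b"] += dlogits.sum(axis=0)
            dpooled = dlogits @ p[f"H{m}_W"].T
            if cfg.include_pooler:
                dpre = dpooled * (1.0 - pooled**2)
                grads["pooler_W"] += pool_pre.T @ dpre
                grads["pooler_b"] += dpre.sum(axis=0)
                dpooled = dpre @ p["pooler_W"].T
            dh = np.zeros_like(h)
            if cfg.pooling == "first_token":
                dh[:, 0, :] = dpooled
            elif cfg.pooling == "last_token":
                dh[:, -1, :] = dpooled
            else:
                dh[:] = dpooled[:, None, :] / h.shape[1]
            if cfg.final_layer_norm:
                dh, dg, db = _layer_norm_backward(dh, fln_cache)
                grads["final_ln_g"] += dg
                grads["final_ln_b"] += db
            head_dx.append(dh)

        dx = np.zeros_like(xs[-1])
        for m in range(cfg.num_layers - 1, -1, -1):
            dx = dx + head_dx[m]
            dx, bg = _block_backward(
                dx, block_caches[m], self._block_params(m), cfg.num_heads
            )
            for k, v in bg.items():
                grads[f"L{m}_{k}"] += v

        if cfg.embedding_layer_norm:
            dx, dg, db = _layer_norm_backward(dx, emb_cache)
            grads["emb_ln_g"] += dg
            grads["emb_ln_b"] += db
        np.add.at(grads["tok_emb"], tok, dx)
        grads["pos_emb"][: tok.shape[1]] += dx.sum(axis=0)
        return float(loss), grads, per_exit_correct

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "format_version": _CHECKPOINT_VERSION,
            "seed": self.seed,
            "config": asdict(self.cfg),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "MultiExitTransformer":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != _CHECKPOINT_VERSION:
                raise ConfigurationError("unsupported checkpoint format version")
            model = cls(MultiExitConfig(**meta["config"]), seed=meta["seed"])
            for k in model.params:
                model.params[k] = data[k].copy()
        return model


def build_model(cfg: MultiExitConfig, seed: int = 0) -> MultiExitTransformer:
    """Deterministically initialized multi-exit transformer."""
    return MultiExitTransformer(cfg, seed=seed)
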