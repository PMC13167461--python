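# Methods

## Exit policies

A multi-exit classifier attaches an affine head `f_m` to the pooled hidden
state `s_m` after each of the `M` transformer layers, yielding per-layer
distributions `p_m` over `K` classes. Confidence at layer `m` is the
normalized Shannon entropy `H_m = −Σ_k p_m^k log p_m^k / log K`, computed
with the natural logarithm internally (the normalization makes the base
irrelevant) and the convention `0·log 0 = 0`. `H_m` is 1 exactly at the
uniform distribution and 0 exactly at one-hot predictions.

The patience counter `P_m` is the run length of consecutive layers agreeing
on the argmax class: it increments when the current argmax equals the
previous layer's and resets to 1 otherwise. Argmax ties are broken to the
lowest class index, deterministically, so the counter is well defined. The
first observed prediction is a run of length 1 (`P_1 = 1`), consistent with
the reset value; a consequence, documented and tested, is that `P_t = 1`
forces an exit at layer 1 for every input.

At each layer the counter is updated **first**, then the exit test is
applied: exit iff `H_m < τ` or `P_m ≥ P_t`, with an unconditional exit at
layer `M`. Two details are deliberate:

* the entropy test is **strict**, so `τ = 0` disables it even for one-hot
  predictions — this is what makes the reduction to the patience-only
  policy exact at the trace level;
* the patience test uses `≥` rather than `=`. Because the counter grows by
  at most 1 per layer from `P_1 = 1`, the two forms first fire at the same
  layer; `≥` is the monotone-safe form.

The update-then-test ordering is the only resolution of the decision rule
that preserves all three structural properties simultaneously: the τ = 0
degeneracy to patience-only, the `P_t = M` degeneracy to entropy-only
(since `P_m ≤ m`, the counter can reach `M` only at the final layer, where
exit is unconditional anyway), and the min-composition identity
`exit(hybrid, τ, P_t) = min(exit(entropy, τ), exit(patience, P_t))`, which
holds because the patience dynamics do not depend on τ. All three are
enforced by tests, both on random trajectories and on trained models, and
an independent brute-force oracle (`exit_layer_oracle`) recomputes the exit
layer from scratch per layer to cross-validate the incremental scan.

The prediction at exit is the argmax of the exit layer's distribution
alone. Combining the exiting layer's prediction with earlier layers'
(e.g. by majority vote) was considered and rejected: no principled
combination rule dominates, and using the current layer keeps the budgeted
and dynamic modes consistent (a dynamic exit at layer m predicts exactly
what a budget of m layers would).

## Backbone and exit heads

The backbone is a pre-norm transformer: token + learned position
embeddings (optionally token-type embeddings and an embedding LayerNorm),
then `M` blocks of multi-head self-attention and a GELU feed-forward
network with residual connections, optionally a final LayerNorm (decoder
convention) and a tanh pooler (encoder convention). Pooling for the heads
is `first_token` for encoder-style models (a reserved classification token
occupies position 0), `last_token` for causal decoder-style, or `mean`.
Exit heads are affine maps `d → K` only — no intermediate nonlinearity —
which keeps their overhead at `M·(dK + K)` parameters; every head,
including layer `M`'s, is freshly trained.

Everything is implemented on float64 NumPy arrays with hand-written
backpropagation. Correctness of the gradients is established by a central
finite-difference check over every parameter family of a configuration
that exercises all architectural options (causal mask, pooler, final
LayerNorm, mean pooling); agreement is at the 1e-7 relative level.

Parameter accounting is closed-form and exact (tested against the
instantiated arrays): embeddings `(V + P + T)·d (+2d)`, per block
`4(d² + d) + (d·F + F) + (F·d + d) + 4d`, plus `2d` for a final LayerNorm
and `d² + d` for a pooler. The published base encoder geometry
(M=12, d=768, 12 heads, F=3072, V=30522, P=512, T=2, pooler) totals
109,482,240 parameters and the base decoder geometry (V=50257, P=1024,
tied output embedding, final LayerNorm, no pooler) 124,439,808 — 109M and
124M truncated. Tied output embeddings contribute no extra backbone
parameters, which is why the decoder needs no special term.

`forward_until_exit` evaluates blocks strictly sequentially, computes each
hidden state once, and stops at the exit layer; an instrumented per-block
call counter lets tests assert that no layer past the exit ever runs and
that the truncated pass is trace-identical to replaying the policy on the
full trajectory.

## Training

All heads and the backbone are jointly optimized against
`L = Σ w_m·CE_m / Σ w_m` with `w_m = m` by default (`linear_cost`): the
cost of reaching exit m is proportional to the m layers executed. A
`uniform` scheme is kept as an ablation switch; the loss is invariant to
rescaling all weights. Probabilities are floored at 1e-12 inside the
logarithm so a confidently wrong head yields a large finite loss.

Defaults: Adam, learning rate 1e-3 (appropriate for the tiny from-scratch
backbone; pretrained-scale models would use ~2e-5), batch 32, 15-epoch cap
with early stopping either on a loss plateau (relative improvement below
1e-4 for 3 epochs) or once the epoch loss falls below 1e-3, at which point
a classification model is converged for all practical purposes. Training
is bit-reproducible for a fixed seed on a given machine.

## Inference modes

* **Budgeted**: one exit layer `m*` for all queries; `select_budget_exit`
  picks the smallest layer maximizing dev-set accuracy (cheapest among the
  best). `m* = M` reproduces conventional full-depth inference exactly.
* **Dynamic**: per-instance policy-driven exits, batch size 1 — matching
  the deployment pattern where requests arrive one at a time. Batching
  across samples with heterogeneous exit layers is out of scope.

Efficiency is reported exclusively as the layer-count speed-up ratio
`1 − Σ m_i/(N·M)`, an affine function of the mean exit layer bounded by
`[0, 1 − 1/M]`. Wall-clock timing is deliberately not measured: it is
hardware-dependent, whereas the layer count is exact, deterministic, and
linear in compute.

## Synthetic data

The corpus generator emulates a multi-class classification task with a
controllable difficulty mixture. One reserved evidence token per class
carries the label signal: easy records place `round(evidence_strength)`
(default 3) copies of the true class's evidence token in the earliest
content positions; hard records hide a single copy at a uniformly random
position among filler tokens drawn from the non-evidence vocabulary.
Defaults — 2,000 samples, K=4, sequence length 16, vocabulary 30, easy
fraction 0.5 — are sized so the 6-layer tiny backbone (d=64, 4 heads,
F=128) trains to convergence in seconds on one CPU. Because the task is
noiseless and separable, a trained model saturates accuracy at shallow
layers; the corpus demonstrates the entropy-depth decline and the
trade-off machinery, not a realistic accuracy ceiling.

The trajectory generator is the stress test for policies: layer-m logits
are i.i.d. `N(0, noise_scale²)` plus a margin `convergence_rate · m` on the
true class, softmaxed. Expected entropy declines with depth (strictly, in
the noise-free case); low rates and high noise produce the oscillating
predictions that exercise patience exits; `label_flip_rate` (default 0.05)
injects irreducible error so accuracy ceilings below 1 are testable.
Defaults (N=1000, M=12, K=4, rate 0.35, noise 0.75) put typical exits in
mid-network for moderate policies. Neither generator emulates the
statistics of any real clinical or imaging dataset: passing tests show the
machinery is correct and exhibits the qualitative phenomena (confidence
grows with depth, easier inputs exit earlier, the hybrid policy spans both
baselines), not that any particular real-data accuracy would be achieved.

## Numerical choices and limitations

* Probability-vector validation tolerance 1e-6 on the sum; LayerNorm
  epsilon 1e-5; init scale 0.02 (normal).
* Checkpoints are versioned NPZ archives with the config embedded as JSON.
* Degeneracy and oracle checks compare full traces (exit layer, prediction,
  entropies, patience counts), not just summary metrics.
* Problem sizes used by the verification script — 10,200 random
  trajectories for the exactness checks, a 2,000-sample corpus with a
  1,600/400 split for the end-to-end cycle — were chosen as comfortably
  large for exact (match-rate) statistics while keeping a full run under a
  minute.
* Limitations: no confidence calibration (e.g. temperature scaling), no
  learned exit controllers, no token-level early exiting for generation,
  no mixture-of-experts layers, no loading of published pretrained
  weights, and no wall-clock or FLOP accounting.
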