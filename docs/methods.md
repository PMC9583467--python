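# Methods

## The problem

Clinical free-text corpora are small: a few hundred labeled reports is a
typical size for a single-site collection, far below what sequence-to-
sequence models normally need.  This package implements a multi-objective
data-enhancement strategy for that regime: define several tasks *on the
same corpus* — here, generating the Impression from the Finding
(summarization), regressing a 6-level severity score, and generating the
Treatment recommendation (the main task) — and let the auxiliary tasks
transfer what they learn to the main task through a shared parameter store.

## Soft parameter sharing

The transfer mechanism is *soft parameter sharing* (SPS).  One global
template tensor `E ∈ R^{p×r×c}` (p slices of r×c reals) holds all shared
knowledge.  Each linear or 1-D-convolution module owns a small kernel
`M ∈ R^{p×p₀×kh×kw}` plus one bias scalar per output slice, and obtains its
weight tensor as

    W = σ(E ⊛ M + b),

where `⊛` is a valid (no padding, stride 1) cross-correlation over the two
spatial axes and `σ` is tanh by default (identity and sigmoid are
selectable).  Valid correlation shrinks each spatial axis by `kernel − 1`,
so a target of shape `(p₀, r₀, c₀)` fixes the kernel shape to

    (p, p₀, r − r₀ + 1, c − c₀ + 1).

A linear weight `n×m` maps to the canonical target `(1, n, m)`; a
convolution kernel `n×n×k` maps to `(k, n, n)`.  Every weight is
regenerated from the template on every forward pass, so gradients of any
task's loss update the template, the kernels and the module-local biases
jointly — training one task literally rewrites the parameter store the
other tasks read.

Embedding tables, vocabulary projections and the scalar severity head stay
dense and module-local: their vocabulary-sized dimension exceeds any
reasonable template extent, and sharing them was never part of the scheme.

### When sharing saves parameters

A templated module costs `p·p₀·(r−r₀+1)(c−c₀+1) + p₀` parameters instead of
`p₀·r₀·c₀`.  The saving therefore depends on the template geometry: with a
template barely larger than the targets (e.g. 105×105 for 100×100 weights,
kernel 6×6, 461 vs 10,100 per module) the shared slope is ~4% of the dense
slope and the one-time template cost (110,250) is amortized after ~11.4
modules.  With a template much larger than its targets (e.g. 96×96 for
64×64 weights, kernel 33×33) the kernels themselves outweigh the dense
weights, and the configuration spends parameters to buy transfer rather
than to save memory.  The parameter report (`mode param-report`) states
both totals for whatever configuration is loaded.

## Task models

All three models are assembled from the same SPS-backed blocks over one
template; hidden size `n` must fit inside the template spatially.

* **Summary** (Finding → Impression): an encoder of L bidirectional LSTM
  layers; the 2n-channel output is folded back to n between layers by a
  pair of n×n linears (one per direction, summed) so every shared weight
  stays n×n.  Each LSTM gate is the sum of two n×n linears (input and
  recurrent); gates f/i/o use the logistic function, the candidate tanh,
  and `h = o · tanh(c)`.  The decoder is an L-layer LSTM whose first layer
  is initialized from the encoder's final states through tanh bridges;
  decoding is teacher-forced in training and greedy at inference.  The
  decoder conditions on the encoder through that state bottleneck only (no
  cross-attention): the design keeps the summary model purely recurrent,
  and memorization/transfer tests confirm it suffices at this scale.
* **Severity** (Finding, Impression → s ∈ [0,1]): one L-layer same-padded
  convolution stack (width k = 3, ReLU between layers) per field, masked so
  padding cannot leak; temporal concatenation; masked global max-pooling
  (chosen over mean-pooling for robustness to variable lengths); an FFN and
  a dense scalar head.  The 0–5 ordinal label is normalized to s = label/5
  so the MSE loss lives on a scale comparable to the cross-entropies when
  losses are summed collaboratively.
* **Treatment (ATR)** (Finding, Impression → Treatment): an encoder–decoder
  Transformer with single-head scaled dot-product attention,
  `softmax(QK^T/√n)V`.  One L-block encoder per source field (self-attention
  then FFN), concatenated along time into the memory; the decoder alternates
  masked self-attention, FFN, cross-attention, FFN, then a dense vocabulary
  projection.  Sinusoidal position encodings are added to √n-scaled
  embeddings.  Each attention/FFN sub-block sits on an additive residual
  path.  Residuals are not optional decoration here: without them the
  uniform-attention initialization is a saddle — in our measurements a
  residual-free stack of this size stays pinned at the marginal token
  distribution (cross-entropy ≈ 3.85 on 16 records) indefinitely, with or
  without SPS.  Layer normalization and multi-head attention are
  deliberately absent.

FFNs are `linear(n→n) → ReLU → linear(n→n)` — the smallest standard form
that keeps every shared weight n×n.  Dropout (default 0.1) follows
embeddings and FFN inner layers and is disabled at evaluation.

## Training

Sequence tasks use mean token-level cross entropy over non-pad positions;
severity uses MSE on the normalized score.  Performance is reported as
MLL = −ln(loss) (natural log, mean loss, so the score is batch-size
independent); larger is better.

The learning-rate schedule is the recurrence

    lr_{i+1} = 0.8 · lr_i · 0.01^{(i+0.01)/(epoch_max+0.01)},   lr_0 = 0.01,

with epoch_max = 40 and epoch index starting at 0 — strictly decreasing and
aggressive (lr falls below 1e-5 by epoch 10).  Optimization is Adam with
global-norm gradient clipping at 1.0; the clip protects the shared template
from a single task's bad batch.

Two orchestration policies:

* **Independent**: train Summary fully, then Severity, then ATR.  Only the
  template carries across phases; optimizer state is reset, so the main
  task starts from a template already shaped by the auxiliaries.
* **Collaborative**: per epoch, the enabled tasks' losses on the same batch
  are weighted (default 1.0 each) and summed before one backward step.

Sequences are optionally wrapped in `<start>`/`<end>` sentinels ("flags");
greedy decoding stops at `<end>` or a length cap and strips the sentinels.

### Learning-rate defaults vs. the reduced scale

The initial rate 0.01 is kept as the configuration default because it is
the reference recipe.  At the reduced scale this package targets (n = 64,
L = 2, template (8, 96, 96), vocabulary ≈ 900), Adam at 0.01 diverges
within one epoch for the severity and treatment models, and the three
tasks tolerate very different rates.  The packaged transfer experiment
therefore starts each independent phase from a per-task rate — 3e-3
(summary), 1e-3 (severity), 5e-4 (ATR) — each chosen by probing that
task's own training trajectory (final train loss and its own dev MLL) at
this scale and picking the healthiest; rates that looked faster but
degraded that same task's loss were rejected.  The memorization driver
uses constant-lr Adam in the same 5e-4–2e-3 range.  None of these rates
was selected by looking at the transfer comparison itself.

## The synthetic corpus

The generator emulates a 513-report thyroid-ultrasound corpus: per record a
Finding, Impression and Treatment token sequence (mean lengths ≈ 60/31/53)
plus a 6-level severity label, split 70/10/20.  Each record is driven by a
latent attribute vector — nodule size class (3), margin regularity (2),
calcification (2), echogenicity (2), vascularity (2), nodule count (3) —
drawn uniformly and independently, which gives every severity label
probability ≥ 0.02.  Severity is the deterministic score
`min(5, size + 2·margin + calcification + hypoechoic + vascular)`.

The Finding renders each attribute as a fixed 2–3-token phrase interleaved
with Poisson-distributed filler (one-parameter length jitter) and 2%
token-substitution noise.  The Impression and Treatment are noise-free
deterministic functions of the attributes (and, for Treatment, the severity
band {0–1, 2–3, 4–5}): fixed key phrases plus per-combination "style"
tokens drawn from a stream keyed by the attribute tuple, sized so the
per-field vocabularies approach the reference distinct-token counts
(353/263/277).  Tokens are abstract ids, not language: the method is
content-agnostic, and only the schema, scale and cross-field coupling
matter for what the tests measure.

What the generator deliberately does not emulate: real clinical phrasing
and grammar, inter-annotator variability in labels, long-tail token
frequencies, and any image/signal modality.  Passing tests therefore show
that the machinery works and that transfer arises when tasks genuinely
share latent structure — not that the method reaches any particular
quality on real reports.

## The transfer experiment

`mode.experiments.transfer_experiment` measures the framework's headline
property at desk scale: for each of 5 training seeds it trains ATR once
with both auxiliaries (independent schedule, 10+10+20 epochs, batch 32) and
once alone (20 epochs), on the default corpus, and compares the seed-mean
test MLL of the two arms.  The claim asserted is directional — auxiliaries
do not hurt, and on average help — not any absolute MLL value: the original
corpus is private, so absolute scores are not reconstructible.  Problem
sizes (n = 64, L = 2, template (8, 96, 96), 513 records, 5 seeds) are the
package's chosen reduced-scale study conditions.

## Numerical choices

* All arithmetic is float64 on a small reverse-mode autodiff core written
  for this package; gradients of every primitive are verified against
  central finite differences in the test suite.
* The SPS correlation and both its adjoints run as circular FFTs of size
  exactly (r, c); the shape calculus guarantees the retained indices are
  free of wraparound, so the result is exact to roundoff.  Kernels with
  1×1 spatial extent take a direct tensordot path, which makes one-hot
  (delta) kernels reproduce template slices bit-for-bit.
* All of a model's kernels with a common spatial extent are carved from the
  template in one batched correlation per forward pass (one template FFT
  instead of one per module).
* Xavier-uniform initialization throughout, seeded; template seed, model
  seeds, batch order and dropout streams all derive from the run seed, so a
  run is a pure function of its configuration.
* Divergence (non-finite loss) aborts training with the offending task,
  epoch and step in the raised error.
* Ties in greedy decoding resolve to the lowest token id (argmax).

## Known limitations

* Template-borne transfer is geometry-sensitive.  At the packaged reduced
  geometry — template (8, 96, 96) with 64×64 targets — every kernel has
  33×33 spatial taps, so each generated weight is a wide projection of the
  template, and a freshly initialized main-task kernel reads the slices the
  auxiliaries wrote only diffusely.  This is the regime the packaged
  transfer experiment probes; the tight-geometry regime (template barely
  larger than its targets, few-tap kernels), where slice-selective reading
  is easiest, is the one the interpretability analyses of such models
  describe.  The experiment asserts the directional claim and reports the
  per-seed numbers it computes either way.
* The no-layer-norm Transformer is stable at the packaged scale but is not
  expected to scale to many layers; that regime is out of scope.
* SPS saves memory only when the template is close in size to its largest
  target (see above); the reduced-scale configuration trades parameters for
  transfer.
* The summary decoder's state-bottleneck conditioning caps how much of a
  long Finding can influence late Impression tokens; adding cross-attention
  would change the model class.
* MLL compares runs on the same corpus and loss only; it is not comparable
  across vocabularies or normalization choices.
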