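# Methods

## Problem and model

`moodgraph` implements a multimodal graph neural classifier for detecting
major depressive disorder (MDD) from paired resting-state EEG and interview
speech. Each sample is represented as two graphs:

* **EEG graph** — one node per electrode (n_e = 128 by default). The binary
  adjacency is the union of two edge sets on the 2-D projected montage:
  local k-nearest-neighbor edges (default k = 4, Euclidean distance,
  symmetrized), and inter-hemispheric edges joining left/right symmetric
  electrode pairs. Hemispheric asymmetry of resting EEG is a known
  depression marker, and the symmetric edges give the network explicit
  cross-hemisphere message-passing routes. The montage does not pin down a
  canonical pair list, so by default each left channel is matched to the
  right channel closest to its mirror image, and a user-supplied pair file
  overrides this.
* **Audio graph** — the recording is cut into n_a = 32 equal-duration
  slices; node j connects to node k iff |j − k| = 1 (a temporal chain).

Initial node features: EEG channels carry per-channel feature vectors
reduced by a single neighbor-mean aggregation,
`h'_v = ReLU(W (e_v ‖ mean_{u∈N(v)} e_u) + b)`; audio slices carry a
580-dimensional row of frame-averaged statistics from seven acoustic
families (MFCC, Mel, pitch, RMS energy, chroma, spectral contrast,
tonnetz — layout documented in `moodgraph.acoustic` and recorded in a
JSON manifest).

The core is a stack of K = 3 units per modality. Each unit applies:

1. **Graph convolution** `H' = σ(D^{-1/2}(A+I)D^{-1/2} H W)`. Self-loops
   are added inside the convolution; normalizing the raw adjacency is
   degenerate for isolated nodes, so the renormalized form is used
   deliberately.
2. **Information-score pooling** `score(v) = ‖row_v((I − D^{-1}A)H)‖₁`,
   keeping the `ceil(pool_ratio · n)` highest-scoring nodes (ties to the
   lower node index, kept in relative order). The row-wise L1 norm follows
   the hierarchical-pooling literature this scoring comes from; L2 is
   available by configuration. D here uses the degrees of the current A
   *without* self-loops; an isolated node's score is the norm of its own
   feature row.
3. **Sparsemax structure learning**
   `E(p,q) = sigmoid(a[H_p ‖ H_q]^T) + λ·A(p,q)`, each row projected onto
   the probability simplex by sparsemax. The result is a sparse,
   row-stochastic and generally asymmetric connectivity that replaces A for
   the next unit — pooling can disconnect related nodes, and this step
   re-estimates the connectivity among the survivors. S is used as-is (no
   re-symmetrization) since the rows are defined as per-node distributions.

Each unit contributes a mean‖max column readout r_k; the graph embedding is
`f_g = Σ_k r_k` (length 2d). With K = 0 — the depth-ablation baseline — f_g
is the readout of the initial features; this convention makes the 0-unit
rows of the ablation grid well-defined.

Fusion: per modality, node-level attention over the initial features
`α = softmax(V tanh(W X₀ + b))`, `f_b = Σ α_i X₀(i,:)` gives a context
vector; the modality embedding is `f_b ‖ f_g`, gated elementwise by
`σ(w_modality)`; the two gated embeddings are concatenated and classified
by one affine layer + softmax (C = 2, MDD positive), trained with
cross-entropy. The attention weights double as interpretability outputs:
per-channel/per-slice α scores and per-family audio gate averages, reported
raw and baseline-subtracted (minimum subtracted).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| k (local edges) | 4 | montage k-NN neighborhood; montage-agnostic, reproducible |
| pool_ratio | 0.5 | nodes kept per unit (ceil, ≥ 1) |
| λ | 1.0 | weight of existing edges inside structure learning |
| K | 3 per modality | unit stack depth |
| hidden_dim d | 32 | conv width; f_g has length 2d |
| sage_dim | 32 | EEG reduction width |
| m'_a | 580 | audio feature row length (full extractor) |
| lr / epochs / batch | 3e-3 / 25 / 256 | Adam, early stop on loss plateau |

The convolution activation is ReLU and the pairwise-score activation is
sigmoid (bounded scores compose well with the λ·A term); both are
configurable. The full audio extractor defaults to 580 columns and the EEG
reduction contract is dimension-agnostic (the published configuration used
600-wide EEG features; any width is accepted). For desk-scale experiments
the training defaults above (d = 32, few epochs) are deliberately small:
the planted-signal fixture is strongly separable and the entire 10-fold CV
must run in minutes on one CPU. These sizes are a package choice, recorded
here so that larger configurations can be restored trivially.

## Differentiation

No deep-learning framework is used; gradients come from a small in-repo
reverse-mode autodiff engine (`moodgraph.autodiff`) covering exactly the
operations the network needs (batched matmul, elementwise nonlinearities,
reductions, gather/concat, softmax, sparsemax with its closed-form
support-restricted Jacobian, a fused cross-entropy). Every primitive is
verified against central finite differences in the test suite, and the
batched training path is asserted equal to the single-graph reference
implementations. Node selection in pooling is discrete: scores are
computed outside the tape and gradients flow only through the selected
rows, which matches the slicing semantics of the pooling step.

## Synthetic fixture: what it emulates and what it does not

The generator reproduces the *layout* of a paired EEG/audio depression
corpus — 22 MDD + 29 HC subjects × 29 segments (638/841 samples), 128
channels, 32 slices — with a planted, recoverable class signal:

* EEG channels carry m_e = 16 band-power-like Gaussian summaries
  (noise_sd = 1.0). MDD adds `effect_size · noise_sd` (default 1.0) to the
  first 6 feature columns of a designated frontal/temporal channel subset,
  with a ±0.5·effect left/right asymmetry.
* Audio rows are family-structured Gaussians (compact 48-column layout);
  MDD shifts Mel means up (+0.5 Δ) and pitch/energy down (−0.8 Δ),
  mirroring the family ranking the attention head should recover. A
  waveform mode instead synthesizes tone-plus-noise clips whose fundamental
  frequency and amplitude drop for MDD, exercising the real feature
  extractor.
* A per-subject random effect (sd 0.2) is shared across a subject's
  segments, so segments are correlated within subject and subject-level CV
  is the honest split.

The fixture is **not** physiological EEG or natural speech: features are
Gaussian, channels are conditionally independent given subject and class,
and no temporal dynamics exist within a segment. Passing tests therefore
demonstrate that the implementation recovers a planted signal of realistic
geometry under subject-level cross-validation — not clinical performance
on real recordings, which requires the gated corpus the layout emulates.

## Evaluation

Cross-validation is stratified at the subject level by default (all
segments of a subject share a fold), with a `segment` option. When k
exceeds the minority-class unit count (e.g. leave-one-subject-out),
stratification is impossible and a plain shuffled split is used. Metrics
are ACC/PRE/REC/F1 in percent with MDD positive, averaged arithmetically
over folds; degenerate denominators yield 0 with a flag. Each fold's model
is re-initialized from a fold seed derived from the run seed, making
reports byte-reproducible. The ablation grid fixes one modality at 3 units
and varies the other over 0–4.

## Numerical choices and degenerate inputs

* sparsemax uses the sort-based exact algorithm; tests compare it against
  an independent bisection solution of the KKT condition.
* k-NN distance ties and pooling score ties break to the lower node index.
* Isolated nodes: zero neighbor-mean in the reduction; score = own-row norm
  in pooling; self-loop keeps the convolution defined.
* Silence in audio: RMS statistics 0, pitch 0 (unvoiced sentinel), never
  NaN; chroma is per-frame inf-norm normalized (gain-invariant).
* Slicing drops remainder samples rather than padding, so every node
  summarizes the same duration.
* All randomness flows from explicit integer seeds (`numpy` Generators).

## Known limitations

* The acoustic DSP (Mel/MFCC/chroma/contrast/tonnetz) is a compact scipy
  implementation of the standard constructions, not a bit-for-bit match of
  any particular audio library; family-level behavior is what the tests
  pin down.
* Dense per-sample adjacencies after structure learning are O(n²); the
  shared first-unit convolution is sparse, but very large montages would
  need sparse structure learning as well.
* Training is CPU-only, minibatch, single-threaded numpy; it is sized for
  the fixture, not for large corpora.
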