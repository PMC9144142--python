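# Methods

This note documents the models and procedures implemented in `psnfuse`, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not show.

## Static similarity

Each static feature contributes a pairwise score in [0, 1] under a declared
rule:

* **age_ratio** — min/max ratio of the two ages. Equal ages (including both
  zero) score 1; a zero age against a positive age scores 0; negative ages
  are rejected.
* **exact_match** — indicator of equality for categorical/Boolean values. A
  missing value on either side is treated as a non-match for that pair.
* **text_onehot** — cosine similarity of multi-hot token-presence vectors.
  Tokens are lowercased, split on commas/semicolons/whitespace, and stripped
  of punctuation; presence rather than counts is used because line-list
  fields name each symptom once. Two empty fields score 1 (both
  symptom-free), one empty field scores 0. One-hot cosine is already
  nonnegative, so no rescaling into [0, 1] is needed.
* **numeric_passthrough** — 1/(1 + |Δ|) for general numeric columns.

The global static similarity is the weighted sum of feature scores with
weights normalized to sum to 1, so the matrix is symmetric with unit
diagonal and entries in [0, 1]. Raw (unnormalized) weights are used only for
weighted-manhattan distances and prioritization-style scoring grids, where a
weight total above 1 is intended.

Missing numeric values are mean-imputed within the matrix being built;
external contextual text embedders enter only through the
`EmbedderAdapter` contract (a pure text → fixed-length vector function; a
file-backed adapter reads precomputed vectors from CSV). No language model
is bundled and all tests run with the one-hot encoder.

## Distance measures and conversion

Five metrics are provided: euclidean, manhattan, cosine (1 − cosine
similarity, with two zero vectors defined as distance 0 with a warning),
chebyshev, and weighted manhattan (Σ w_d |x_d − y_d|, weights required).
Distances convert to similarities by s = 1/(1 + d): bounded, strictly
monotone, parameter-free. A gaussian kernel exp(−d²/σ²) with σ the median
off-diagonal distance is available as an alternative for kernel-style
workflows; the inverse form is the default everywhere.

## Sequence autoencoder

Variable-length visit sequences are compressed to one vector per patient by
an LSTM encoder-decoder:

* per-visit input projection e_t = ReLU(W_v x_t + b_v) into the hidden
  width;
* LSTM encoder (default 1 layer, hidden/embedding width 32, supported
  range 5-64); the embedding is the final hidden state;
* repeat-vector decoder: the embedding is fed to a decoder LSTM at every
  output step, followed by a linear readout to feature space;
* loss: mean squared reconstruction error on z-scored features (per-feature
  standardization over all visits; only embeddings are consumed downstream,
  so no inverse transform exists).

Because no deep-learning framework is a dependency, the network is written
directly on numpy: the forward pass, backpropagation through time, and Adam
(lr 1e-3, β = 0.9/0.999) with global-norm gradient clipping at 5. Gradient
correctness is pinned by central finite-difference checks over all parameter
groups in the test suite. Sequences are batched by exact length (padding-
and mask-free); each iteration samples one length bucket with probability
proportional to its patient count and takes one Adam step on a minibatch of
at most 32 sequences. The default budget is 3,000 iterations — the
reconstruction loss on realistic visit data stabilizes within a few
thousand — with no early stopping; tests and the reproduction script use
300-2,000 iterations, which this data comfortably converges within. A fixed
seed determines initialization and batch order, making training bitwise
reproducible. NaN loss aborts with a diagnostic rather than continuing.

## Network fusion

Given static and dynamic similarity matrices on the same patient index:

1. **row_normalize** — divide each row by its sum (all-zero rows become
   uniform with a warning, keeping later iterations finite);
2. **symmetrize** — (W + Wᵀ)/2, exact and idempotent;
3. **knn_localize** — keep each row's K strongest off-diagonal links and
   renormalize the kept weights to sum 1. Ties at the K-th neighbor break
   toward the lower patient index; the result is generally asymmetric and is
   deliberately not re-symmetrized. By default each matrix ranks its own
   rows (`neighbor_source="self"`); ranking by the average of both matrices
   (`"union"`) is available, since "nearest neighbors from both matrices" is
   ambiguous;
4. **iterate** — MP¹ ← (wts·S′ + (1−wts)·MP²)/2 and MP² ← (wtd·D′ +
   (1−wtd)·MP¹)/2 for T rounds (default 20), starting from the
   normalized-symmetrized (pre-localization) matrices; starting from the
   localized matrices is a config switch. The localized matrices are the
   static terms S′/D′ of the recursion. A convergence mode stops when the
   largest elementwise change drops below 1e-9;
5. **FM** = (MP¹_T + MP²_T)/2, symmetrized.

The recursion is affine with two-step contraction factor
(1−wts)(1−wtd)/4 < 1, so it has a unique fixed point with the closed form
implemented in `snf_fixed_point`; the iterated and analytic answers agree to
1e-10 in the acceptance suite. Because the /2 averaging shrinks absolute
values toward that fixed point, fused entries are interpreted ordinally (as
a ranking of pairs) rather than as calibrated similarities, and no final
row-normalization is applied. The classic message-passing fusion
(P ← S·P·Sᵀ) is included only as a clearly labeled comparison baseline.

## Evaluation

Pairwise mode scores every unordered pair: predicted-similar by a global
threshold, per-patient top-K (symmetrized by OR: the pair counts if either
patient lists the other), or top-p% of the cohort; truth is exact outcome
equality, which generalizes the binary died/survived reading to multi-class
outcomes. Accuracy, recall, precision and F1 follow the standard confusion
formulas with zero divisions returning 0 and a flag.

Patient-level mode predicts each held-out patient's outcome by majority
vote among its K most-similar training patients (K may be given as a
percentage p of the training fold, K = ⌈p/100 · |train|⌉). Vote ties break
to the most frequent class in the training fold, then to the lower class in
sorted label order; similarity ties keep the lower patient index. Folds are
stratified by outcome (falling back to unstratified with a warning when a
class has fewer members than folds), shuffled under a recorded seed, and
accuracies are reported as mean ± population std across folds, as
percentages to two decimals.

## Synthetic cohorts

The generators draw the outcome first and generate features conditional on
it, so the signal strengths have a clean operational meaning: β = 0 makes a
channel's features independent of the outcome, β = 1 maximizes the
class-conditional effects.

* **Static cohort** (default N = 155, 4 classes): ages Uniform(18, 90)
  shifted ~18·β years between adjacent classes; gender an unbiased coin
  (deliberate pure-noise feature); a class-biased Boolean chronic flag
  (p = 0.5 ± 0.45·β); three text fields drawing tokens from per-class
  disjoint pools with probability β, else from the shared pool — at β = 1
  between-class text similarity is exactly zero.
* **Longitudinal cohort** (binary outcome): visit counts on [2, 10] from a
  distribution peaked near 7; a latent trajectory (default 3-dim) whose
  starting level and per-visit drift are class-shifted by β_d, mapped
  through a fixed loading matrix to 7 primary measurements around realistic
  baselines (BMI, systolic/diastolic pressure, total/HDL/LDL cholesterol,
  triglycerides) plus Gaussian noise; non-HDL and the cholesterol/HDL ratio
  are derived exactly from the generated values. The static profile adds
  age and three class-biased Boolean risk flags (smoke, diabetes,
  hypertension medication).

What passing tests on these cohorts show: the pipeline recovers planted
class structure from both channels, fusion does not destroy it, and
no-signal cohorts yield chance-level accuracy. What they do not show:
performance on real clinical data, whose feature distributions, missingness
patterns, text vocabulary, and label noise the generators make no attempt to
match beyond field names, types and shapes.

## Numerical and reproducibility choices

* All reductions run in fixed patient-index order; no parallel
  nondeterminism. Re-running any stage with the same resolved config is
  bit-identical.
* Similarity matrices round-trip through CSV at ≤1e-12; NaN entries are a
  hard write error.
* Problem sizes in the test and reproduction runs (N = 150-300 patients,
  10 seeds for the end-to-end benchmark, 300-500 autoencoder iterations)
  were chosen as the smallest cohorts at which the planted-signal effects
  are stable; all complete in minutes on one CPU.

## Known limitations

* The fused matrix's absolute scale is not meaningful; only rankings are.
* The one-hot text encoder ignores token semantics (synonymous symptoms are
  orthogonal); richer encodings must come through the adapter.
* The autoencoder supports stacked layers but defaults to one; no attention,
  denoising, or bidirectional variants.
* Multi-class pairwise evaluation treats any label mismatch as
  "non-similar"; no partial credit between related outcomes.
* No survival-time modeling: outcomes are nominal classes only.
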