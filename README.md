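# psnfuse

Multi-model **patient similarity networks** (PSNs) for heterogeneous clinical
data: a static channel scoring per-feature similarity of patient profiles, a
dynamic channel embedding variable-length visit sequences with an LSTM
autoencoder, and a pairwise similarity-network-fusion step that merges both
into a single fused PSN used for outcome classification.

## Who this is for

Researchers working with cohort data that mixes a **static profile** per
patient (demographics, Boolean risk flags, free-text symptom or
chronic-disease fields) with **longitudinal visit records** (a different
number of visits per patient, each a fixed-width vector of measurements such
as BMI, blood pressure, and lipid panels). The package builds a
patient-by-patient similarity matrix from each data type, fuses them, and
evaluates how well the resulting network predicts a patient outcome by
k-nearest-neighbor majority vote under cross-validation.

## The model

**Static channel.** For patients *i*, *j*, each selected feature *k* gets a
similarity score *fs<sup>k</sup><sub>ij</sub>* ∈ [0, 1]: the ratio
min(age<sub>i</sub>, age<sub>j</sub>)/max(age<sub>i</sub>, age<sub>j</sub>)
for ages, an exact-match indicator for categorical/Boolean fields, and the
cosine of one-hot (multi-hot bag-of-tokens) encodings for free-text fields.
The static patient similarity is the weighted sum

&nbsp;&nbsp;&nbsp;&nbsp;STPS<sub>ij</sub> = Σ<sub>k</sub> w<sub>k</sub> · fs<sup>k</sup><sub>ij</sub>, &nbsp; Σ<sub>k</sub> w<sub>k</sub> = 1,

collected into the static similarity matrix STM.

**Dynamic channel.** Each patient's visit sequence V<sub>1..m</sub> is
projected per visit through e<sub>t</sub> = ReLU(W<sub>v</sub>V<sub>t</sub> +
b<sub>v</sub>), run through an LSTM encoder, and summarized by the final
hidden state (default 32-dim). A repeat-vector LSTM decoder reconstructs the
sequence and the model trains on mean squared reconstruction error; the
network is implemented directly on numpy (forward, backpropagation through
time, Adam) with gradients pinned by finite-difference tests. Pairwise
distances between embeddings (euclidean, manhattan, cosine, chebyshev, or
weighted manhattan), converted through s = 1/(1 + d), give the dynamic
similarity matrix DM.

**Fusion.** Both matrices are row-normalized, symmetrized as
(W + Wᵀ)/2, and sparsified to each row's K strongest links (renormalized).
The coupled recursion

&nbsp;&nbsp;&nbsp;&nbsp;MP¹<sub>t+1</sub> = (wts·STM′ + (1−wts)·MP²<sub>t</sub>)/2, &nbsp;
MP²<sub>t+1</sub> = (wtd·DM′ + (1−wtd)·MP¹<sub>t</sub>)/2

runs T rounds and the fused PSN is FM = (MP¹<sub>T</sub> + MP²<sub>T</sub>)/2.
The recursion is affine and strictly contractive, so it has a unique fixed
point that `snf_fixed_point` computes in closed form — an exact oracle for
the iteration.

**Evaluation.** A similarity matrix is scored by pairwise confusion counts
(a pair predicted similar is a true positive when the outcomes agree) or by
patient-level KNN outcome prediction under stratified 5-fold
cross-validation, including top-p%-of-training neighborhood restriction.

## Worked example

```python
import psnfuse as pf

recipe = pf.CohortRecipe(n_patients=120, n_classes=2,
                         beta_static=0.8, beta_dynamic=0.8, seed=7)
static, visits = pf.make_longitudinal_cohort(recipe)
print(f"patients: {static.n_patients}, visit rows: {visits.total_visits}")

stm = pf.build_static_psn(static)
cfg = pf.AutoencoderConfig(n_features=9, embedding_dim=16, n_iterations=300, seed=7)
dsm, model, emb = pf.build_dynamic_psn(visits, cfg)
print(f"embeddings: {emb.vectors.shape}, final training MSE: {model.loss_history[-1]:.3f}")

fm = pf.fuse_psns(stm, dsm, pf.FusionConfig(K=12, T=20, wts=0.5, wtd=0.5))
outcomes = static.outcome.to_numpy()
for name, m in (("static", stm), ("dynamic", dsm), ("fused", fm)):
    mean, std = pf.knn_cv_accuracy(m, outcomes, k=5, folds=5, seed=7)
    print(f"{name:8s} 5-fold KNN accuracy: {100*mean:.2f}% +- {100*std:.2f}%")
```

Output:

```
patients: 120, visit rows: 809
embeddings: (120, 16), final training MSE: 0.237
static   5-fold KNN accuracy: 92.50% +- 3.12%
dynamic  5-fold KNN accuracy: 95.83% +- 4.56%
fused    5-fold KNN accuracy: 95.83% +- 4.56%
```

The 809 visit rows collapse to one 16-dim embedding per patient; with strong
planted signal in both channels (β = 0.8), each single-channel PSN predicts
the binary outcome well and the fused PSN matches or exceeds both.

The same pipeline is available from the shell:

```bash
psnfuse simulate --kind longitudinal --n 120 --seed 7 --out run/
psnfuse static  --static-csv run/static.csv --seed 7 --out run/stm/
psnfuse dynamic --static-csv run/static.csv --visits-csv run/visits.csv \
                --embedding-dim 16 --seed 7 --out run/dsm/
psnfuse fuse    --static-csv run/static.csv --stm-csv run/stm/stm.csv \
                --dsm-csv run/dsm/dsm.csv --seed 7 --out run/fm/
```

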