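# Methods

## Problem and model

`pepgraph` identifies multi-functional peptides: short sequences (typically
5–50 residues) that may carry several function labels at once (e.g. a
peptide that is both anti-microbial, AMP, and anti-cancer, ACP).  The
multi-label problem is recast as **graph node classification** over a
function-label graph:

1. **Peptide representation.**  A sequence is mapped to a fixed-dimension
   vector *p* by one of three encoders: a composition descriptor (AAC,
   PAAC, DP or CTDD), a small trainable transformer encoder with a tanh
   pooler over a prepended start token, or a lookup adapter for
   representations precomputed by an external protein language model.
2. **Node feature encoder.**  For each of the M labels, an independent
   linear map produces a node feature h_i = dropout(W_i · p).  Every node
   therefore starts as a label-specific view of the same peptide.
3. **Graph attention.**  Two stacked multi-head GAT layers over the fully
   connected label graph (self-loops included) update the node features.
   Attention logits are LeakyReLU(a_srcᵀ W h_i + a_dstᵀ W h_j), softmax-
   normalized over the neighborhood; the K per-head outputs are
   concatenated, so K · d_head must equal the node dimension.  The hidden
   layer uses an ELU nonlinearity; the output layer is linear before the
   classifiers.
4. **Node classifiers.**  Per-node logistic heads res_i = σ(W_i · h′_i + b_i)
   give one probability per label; a label set is obtained by thresholding
   (0.5 for evaluation, 0.95 in high-confidence screening).

Training minimizes the mean binary cross-entropy over all peptide × label
entries with AdamW (decoupled weight decay 0.01) in two parameter groups:
encoder parameters at `encoder_lr` (default 5e−5) and graph parameters at
`gat_lr` (default 1e−3).  Optional **FGM adversarial training** runs, per
batch, a clean pass, perturbs the designated embedding parameter by
r_adv = ε·∇L/‖∇L‖₂ (ε default 0.5; equivalently −ε·g/‖g‖₂ for the score
gradient g = ∇ log p), accumulates gradients from a second pass at the
perturbed point, restores the parameter and takes one optimizer step on
the summed gradients.  Both passes replay the same dropout noise, so ε = 0
degenerates exactly to a doubled clean pass.  The perturbation site is the
token-embedding table for the transformer encoder and the projection
weight for composition encoders; a composition encoder without a
projection cannot train adversarially and says so.

The standard protocol trains `n_repeats` models (default 10; the desk-scale
benchmarks here use 3) from consecutive seeds and averages predicted
probabilities arithmetically before thresholding.

## Numerical core

No GPU framework is assumed: the package carries its own small reverse-mode
automatic-differentiation engine on numpy arrays (`pepgraph._autodiff`),
supporting broadcasted arithmetic, batched matmul, softmax, the activations
above, reductions, concatenation and integer gathering.  Gradients are
validated against central finite differences in the test suite (relative
error ≤ 1e−4 on the transformer path; spot checks through the full GAT
model agree to ~1e−7).  Probabilities are clamped to [1e−7, 1−1e−7] inside
the loss; the sigmoid is computed in its numerically stable split form;
softmax subtracts the row maximum.

### Feature scaling

Composition descriptors are z-scored per dimension on the training set
before the learned projection (`standardize=True` in the standard model
recipe).  This matters more than it may look: DP vectors sum to 1 per
400-entry tier, so raw entries are ~1e−3, attention logits downstream come
out at ~1e−4, and every GAT softmax collapses to the uniform distribution —
the GAT silently degenerates into unweighted feature pooling and its
attention carries no information.  With standardization the attention is
sharply input-dependent and the interpretability statistics below become
meaningful.  The scaler is part of the checkpoint.

## Evaluation metrics

For true/predicted label sets L, L* over M labels, averaged over samples:
precision |L∩L*|/|L*|, coverage |L∩L*|/|L|, accuracy |L∩L*|/|L∪L*|,
absolute true 𝟙[L = L*], and absolute false (|L∪L*|−|L∩L*|)/M.  Conventions
for degenerate sets: an empty prediction against a non-empty truth scores 0
(penalized); two empty sets are an exact match and score 1.  These
conventions preserve the ordering absolute true ≤ accuracy ≤
min(precision, coverage).  Per-class sensitivity TP/(TP+FN) and specificity
TN/(TN+FP) are computed one-vs-rest; a label with no positives has
*undefined* (NaN) sensitivity with a warning, never a silent 0.  All metric
code is checked against an exact rational-arithmetic oracle.

## Interpretability

* Residue importance d_j = Σ_i β_ij sums the encoder attention received by
  position j; each L×L attention map conserves Σ_j d_j = L.
* Node connection r = γ + γᵀ symmetrizes a GAT attention matrix; total mass
  is exactly 2M per matrix.
* Function correlation counts, over samples × attention matrices, the
  off-diagonal pair (i, j) with maximal r_ij.  Ties split the count
  fractionally (1/n_ties each), keeping conservation exact; diagonals are
  excluded (a self-connection is not a function pair).  Because a single
  desk-scale model's argmax pair is noticeably seed-dependent, the
  package's protocol pools counts across the repeat ensemble's matrices
  (models × layers × heads), the desk-scale analogue of enumerating all
  attention heads of a large encoder.

## Synthetic benchmark

The generator emulates the structure of curated bioactive-peptide corpora:
M labels with strong class imbalance, a minority of peptides carrying
exactly two correlated labels, and never more than two.  Each label is a
3–6-residue motif implanted at a uniform non-overlapping position into
i.i.d. background sequence (uniform residue frequencies by default; a
Swiss-Prot-like preset ships with the package), with independent
per-residue mutation of the implant.  A manifest records implant spans for
ground-truth checks.  The reference fixture is 5 labels (ACP, ADP, AHP,
AIP, AMP), n = 2000, lengths 10–40, mono-label proportions
0.40/0.25/0.15/0.12/0.08 (AMP/AHP/AIP/ACP/ADP), a 5% (ACP, AMP) dual-label
fraction, 10% motif mutation, fixed seed.  A trivial motif-substring
classifier reaches absolute true ≥ 0.95 at zero mutation, calibrating
learnability before any model training.

What the generator does **not** emulate: real physicochemistry, homology
structure, length/composition couplings, or label correlations beyond
motif co-occurrence.  Consequently, passing the synthetic benchmarks shows
that the pipeline recovers implanted sequence signal and label structure —
not that it matches real-data performance.

### Default feature choice

DP (distance-pair) is the default composition descriptor because the
benchmark's signal lives in residue adjacency: on the reference fixture a
linear baseline reaches test absolute true ≈ 0.87 on DP but only ≈ 0.63 on
AAC/PAAC and ≈ 0.43 on CTDD, which marginalize order away.  The DP
"distance" convention is the number of intervening residues (g = 0 means
adjacent), with each distance tier normalized separately.

### A negative result on the GAT ablation

On this synthetic family the with-GAT and without-GAT variants tie (test
accuracy 0.807 vs 0.808 at n = 2000 over 5 seeds; the simpler variant wins
at n = 600).  This is expected on reflection: predictions threshold each
label independently, so graph coupling can only improve per-label marginal
estimates, and under the generator's correlation structure (one motif per
label plus pair co-occurrence) a shared-representation independent
classifier already captures everything usable.  GAT gains reported on real
peptide corpora involve data structure and representation scales this
generator deliberately does not simulate; the corresponding acceptance
check is left in place and fails honestly.

## Tunable parameters (defaults)

| parameter | default | notes |
|---|---|---|
| epochs / batch size | 100 / 32 | full passes over the training split |
| encoder_lr / gat_lr | 5e−5 / 1e−3 | AdamW, weight decay 0.01 |
| FGM ε | 0.5 | Euclidean norm of the perturbation |
| n_repeats | 10 (3 at desk scale) | repeat-and-average ensembling |
| GAT layers / heads / head dim | 2 / 4 / 8 | desk scale; 2 / 6 / 128 mirrors the full-size recipe |
| node dimension d_node | 32 | must equal heads × head dim |
| dropout (encoder, node) | 0.1 / 0.1 | independently configurable |
| LeakyReLU slope | 0.2 | attention logits |
| decision threshold | 0.5 | 0.95 for screening |
| dataset filters | 5–50 aa, ≥40 per class | preprocessing defaults |
| screening filters | 4–40 aa, threshold 0.95 | exact-duplicate dedup |
| PAAC λ / weight | 4 / 0.05 | classic property triple |
| DP max distance | 1 | tiers g = 0, 1 |

Problem sizes used by the shipped tests and the acceptance script — n = 2000
fixtures, 3-repeat ensembles, 100 epochs, 5-seed ablations — are the
package's desk-scale study conditions; the full-size recipe (768-dim
representations, 6×128 GAT heads, 10 repeats) is configuration, not code.

## Design choices where the design was open

* Self-loops are included in every node's neighborhood (standard GAT).
* "Edge weights initialized to 1" is realized as an all-ones adjacency
  mask; effective weights are the learned attention coefficients.
* Clean and adversarial losses are summed unweighted; the FGM norm is the
  global norm over the whole gradient tensor.
* Node classifiers include bias terms.
* The train/test split is per-peptide and unstratified by default (a
  stratified option exists).
* Duplicate removal in screening is exact sequence-string matching after
  upper-casing; near-duplicate (similarity-based) removal is out of scope,
  as is redundancy clustering (a hook accepts a precomputed representative
  id list).
* Screening ranks candidates by the weakest required-label probability,
  descending.
* Tokenization for the internal encoder: the 20 residues plus start / end /
  pad / unknown; external representation providers own their tokenization.

## Known limitations

* The internal transformer encoder is a desk-scale stand-in; it is not
  pre-trained, and nothing here reproduces masked-token pre-training.
* GAT attention interpretability at desk scale is only meaningful in
  aggregate (pooled over the repeat ensemble); single-model argmax pairs
  are seed-noisy.
* Metrics treat all labels symmetrically; no probabilistic calibration or
  ranking-based measures (AUROC/AUPRC) are provided.
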