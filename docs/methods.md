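# Methods

## Problem and model

Drug-combination synergy is framed as binary classification of
(drug 1, drug 2, cell line) triples. A triple's label is the majority vote
of the signs of its reference-model synergy scores (Bliss, Loewe, HSA,
ZIP; score > 0 votes synergistic). A 2–2 tie falls back to the sign of the
mean score, and a tie with exactly zero mean is dropped: this uses all
available information and is deterministic. Scores missing for individual
models simply abstain. Every unordered combination is expanded into both
drug orders with the same label; duplicate measurements of one unordered
triple are merged by majority vote over their labels, ties dropped and
logged.

The classifier combines two views:

* **Coarse.** A four-layer spectral hypergraph convolution over nodes =
  drugs ∪ cell lines with one hyperedge per training triple,
  X′ = σ(D_v^(−1/2) H D_e^(−1) Hᵀ D_v^(−1/2) X Θ) with identity hyperedge
  weights, ReLU, and dropout between layers. The final layer convolves the
  sum of the third layer's output and a linear projection of the input
  features (a pre-convolution residual). Node inputs are linear projections
  of the molecular embedding (drugs) and the cell-line embedding.
* **Fine.** Per-layer substructure tokens from the drug encoder and a
  projected cell-line token interact through four-head scaled dot-product
  cross-attention over the three set pairs (A↔B, A↔cell, B↔cell), run in
  both query/key directions and pooled by the mean over query positions —
  six vectors, ordered (A←B, B←A, A←cell, cell←A, B←cell, cell←B). The six
  then pass through self-attention and one linear layer shared across the
  six positions; their concatenation is the fine representation.

The drug encoder is a three-layer GIN (two-layer ReLU MLP per layer,
non-learnable ε = 0 by default) with a self-attention pooling readout per
layer: a one-layer symmetric-normalized GCN scores atoms, the top
⌈ratio·n⌉ atoms (ratio 0.5) are retained with features gated by tanh of
their score, and the mean over retained atoms is the layer's token.
Jumping-knowledge concatenation of the tokens plus a linear projection
gives the molecular embedding. Ablation variants swap GIN for GCN or
multi-head GAT and the readout for add/max/mean pooling. Cell lines are
encoded by a two-layer ReLU MLP over z-scored expression.

Fusion is a single highway layer, y = T⊙G(x) + (1−T)⊙x with sigmoid
transform gate T and ReLU transform G, followed by a two-layer MLP and a
2-way softmax; the positive-class probability is reported and thresholded
at 0.5.

## Objective

L = w_cls·CE + w_rec·L_rec + w_con·L_con, default weights (1.0, 0.1, 0.1)
(classification-dominant; fully configurable, and the ablation harness
sweeps them). L_rec is the mean squared difference between pairwise cosine
similarities of the hypergraph node embeddings and of the original
descriptors, computed separately for the drug block (ECFP6 fingerprints)
and the cell block (expression rows) and averaged — the two descriptor
spaces are incommensurable, so no cross-block target exists. Zero-norm
descriptor rows get zero cosine rows and are logged. L_con is a margin
hinge in the hypergraph embedding space with distance 1 − cosine (scale
free, consistent with L_rec): positives are pulled toward the positive
centroid and, per positive anchor, one sampled negative (1:1, with
replacement only if negatives are scarce) is pushed beyond margin m = 0.5
(cosine distance lives in [0, 2]). Single-class batches skip the term with
a warning. A sample's embedding is the concatenation of its two drug node
and cell node vectors from the coarse module.

Optimization is full-batch Adam at 4e-4 for up to 2000 epochs with early
stopping on validation cross-entropy (patience 50, min-delta 1e-4,
best-validation weights restored); all of initialization, dropout (0.3),
and negative sampling derive from one seed, so runs are bit-reproducible.

## Preprocessing

SMILES are canonicalized, then featurized into 78-dimensional binary atom
vectors: one-hot atom type over 43 named elements plus an "other" bucket
(44), one-hot heavy-atom degree, total hydrogen count, and implicit
valence (0–10 each, values above 10 clamped into the last bucket), and an
aromaticity flag. Fingerprints are 1024-bit extended-connectivity
fingerprints of diameter 6 — Morgan radius 3, the standard reading of the
"ECFP6" name; a `fp_radius` option preserves a literal radius-6 variant.
Expression is restricted to a landmark gene list and standardized per gene
((x − μ)/σ, population σ, tolerance 1e-6); zero-variance columns are
dropped and missing values imputed with the (training) column mean, both
logged. When a split is supplied, normalization statistics come from
training rows only to avoid leakage; otherwise full-data statistics are
used and recorded.

## Cross-validation

All three scenarios are grouped five-fold splits with fold k as test and
fold k+1 (mod 5) as validation (3:1:1). Groups are unordered triples
(random scenario — so a sample and its mirrored twin always co-partition),
unordered drug pairs, or cell lines. Validation groups are held out at the
group level too, so early stopping cannot see held-out pairs or cell
lines. Folds are balanced by group count (deterministic permutation +
even split). Hyperedges are built from training samples only, and
evaluation asserts the incidence matrix is unchanged afterwards; entities
unseen at training time are isolated nodes that self-propagate through the
convolution (identity row in the normalized operator).

## Synthetic study

The generator emits 30 drugs, 12 cell lines, 64 genes and 600 scored
triples (seed 7) with a planted rule: a triple is synergistic iff both
drugs carry a pyridine motif AND the cell line is sensitive. Drugs are
assembled from valid SMILES fragments (alkyl chains, benzene/cyclohexane
cores, amide/halogen/hydroxy terminals), with motif prevalence 0.95.
Sensitivity is an intrinsic latent attribute of 1/3 of the cell lines,
drawn independently of the expression clusters (3 clusters, cluster mean +
unit Gaussian noise). This independence is deliberate: if sensitivity were
readable from expression, a model could generalize it to held-out cell
lines and the leave-cell-line-out scenario would not probe the
unseen-entity regime. With motif prevalence p = 0.95 and sensitive
fraction s = 1/3, the positive rate is p²·s ≈ 0.3, and the only signal
available for an unseen cell line is the motif, capping leave-cell-line-out
ranking far below the random-CV regime. Reference-model scores are
latent-sign · |N(2, 1)| plus per-model N(0, 1.5) disagreement noise, so
majority voting (including occasional 2–2 ties) is exercised while
recovering ≥ 95% of latent labels.

What passing these tests shows — and does not: the pipeline can recover a
clean, fully observable decision rule (random-CV AUC ≈ 0.96) and degrades
when cell identity is withheld (mean leave-cell-line-out AUC ≈ 0.36–0.74
depending on the seed that assigns the 12 cell lines to folds — per-fold
AUC is high-variance with only 2–3 test cell lines, though the drop versus
random CV is large for every seed we ran). Real screens have noisier
labels, correlated chemistry, and expression that partially predicts
sensitivity, so absolute numbers here do not transfer.

## Run-scale choices

Tests and the acceptance script use a reduced architecture (GIN
[32, 32, 32], cell MLP [64, 48], coarse stack [96, 48, 48, 48], head 64,
200 epochs, patience 30) appropriate to the 1200-sample toy study; the
estimator defaults remain the full configuration (GIN [128, 128, 128],
cell MLP [512, 384], coarse [768, 384, 384, 384], head 256, 4 heads,
dropout 0.3, Adam 4e-4, ≤2000 epochs).

## Numerical and degenerate-input conventions

Tied pooling scores retain the lower atom index (stable sort);
single-atom molecules always retain their atom, and min-max atom-importance
normalization maps a constant layer to 1.0. Softmax is computed with a
constant max shift; cosine computations add 1e-8 to norms. Self-pairs
(drug1 = drug2) are excluded by default (configurable), since
self-combination "synergy" is not meaningful. The hyperedge set defaults to
all training triples (`hyperedges="all"`), maximizing connectivity; a
`positive_only` mode restricts to synergistic triples for the reading that
hyperedges encode synergy itself.

## Known limitations

No bond features, stereochemistry, 3D conformers or multi-omics inputs;
hyperedge weights are fixed at identity; leave-out generalization is
intrinsically limited by isolated hypergraph nodes (the coarse view
contributes nothing new for unseen entities); training is full-batch and
CPU-bound, sized for datasets of order 10³–10⁴ samples, not full public
screens.
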