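# Methods

## Model and assumptions

`plkd` treats cell-type annotation and batch integration as one multi-task
problem. The premise: gene-level expression is batch-sensitive, but the
joint activity of functionally related gene sets ("patterns") is not, the
way a species stays recognizable across camera angles. The Teacher therefore
never attends over genes — it attends over m pattern tokens, each a masked
linear projection of the expression vector restricted to one pathway's
genes.

Inputs are cells × genes matrices (raw UMI counts or pre-normalized),
reference labels, optional batch labels, and pathway gene sets in GMT
format. ATAC data is accepted only as a precomputed gene-activity matrix in
the same gene space. Counts are normalized by scaling each cell to the
median library size and applying log1p; query data are normalized with
query-derived size factors (the reference's factors are not exported — the
two conventions agree up to a global scalar absorbed by the first linear
layer, and per-dataset factors keep query processing independent of the
reference archive).

### Teacher

- Navigator: m parallel maps W_j (n × h), h = 48 by default; m equals the
  GMT pathway count in knowledge mode, 64 in maskless mode. Initialization
  is Kaiming-uniform with fan-in counted over unmasked rows only, so a
  25-gene pathway's token has the same scale as a dense one.
- Mask mode `persistent` (default) re-applies the binary mask in every
  forward pass and to every gradient, so masked weights are *exactly* zero
  at all times — the pattern-to-pathway interpretation depends on this. The
  `init_only` mode (mask applied only at initialization) exposes the weaker
  reading in which training may repopulate masked entries.
- Attention: one layer, two heads, scaled dot-product with 1/√d_head
  (d_head = h/2). No positional encodings: patterns are a set. Residual
  connection + layer norm are off by default and available via
  `transformer_extras` for ablation; the classifier is a single linear
  layer h → k (`classifier_hidden` inserts one ReLU layer).
- The updated cls position is the cell embedding c_r used for all
  integration metrics and visualization.

### Objectives

- L1 normalizes each pairwise term by √(Y_a S Y_aᵀ · Y_b S Y_bᵀ). The
  unnormalized product denominator is available via `raw_denominator`, but
  only the square-root (cosine) form is scale-invariant and satisfies
  "orthogonal → 0, identical → 1" per pair. The similarity kernel uses
  squared Euclidean distance (bandwidth-1 Gaussian); `squared=False` gives
  the plain-norm variant. S is computed per minibatch — the N × N kernel
  over a full atlas is both infeasible and unnecessary, since the loss only
  needs within-batch geometry.
- L1 is applied to softmax probabilities of the Teacher logits (bounded
  soft assignments); L2 is standard mean cross-entropy.
- L3 is KL(teacher ‖ student) under temperature-T softmaxes, T = 3. The
  trainer multiplies its gradient by T² (`distill_rescale`), the standard
  correction that keeps the distillation signal's magnitude independent of
  T; without it the tempered gradient is O(1/T) and the Student fails to
  converge within the epoch budget. The loss *value* is reported
  unrescaled.
- L4, self-entropy of the batch-mean Student logits, has two readings. The
  literal form −(1/k) Σ_a ȳ_a log softmax(ȳ)_a is implemented and is the
  `self_entropy_loss` default, but it is unbounded below (send one mean
  logit to −∞ and the loss falls like −t²/k), so it cannot be minimized;
  the trainer therefore defaults to `self_entropy_mode="shannon"`, the
  Shannon entropy of softmax(ȳ). Even the bounded form is
  class-collapse-prone at full weight — its minimum concentrates the mean
  prediction on one class — so λ4 defaults to 0.1 against λ3 = 1.

### Training

Sequential: Teacher to convergence (6 epochs, minibatch SGD, momentum 0.9,
cosine-decayed lr), then the Student against the frozen Teacher's logits.
Defaults: batch size 256, Teacher lr 0.02, Student lr 0.05 (the plain MLP
both tolerates and needs a larger step than the attention stack at the same
epoch budget), global-norm gradient clipping at 5.0 (the clustering loss
occasionally produces large embedding gradients early in training). All
randomness flows from one seed; runs are single-threaded deterministic, and
identical configs reproduce bitwise-identical loss logs. Reference labels
never reach the Student; `use_hard_labels` adds an L2 term for
experimentation but is off by default.

### Interpretability

- Pattern gene sets: genes whose row sum of W_j strictly exceeds the mean
  row sum. With the persistent mask these are always a subset of the
  pathway, so in knowledge mode the GMT itself is the explanation and the
  extraction mainly serves maskless models.
- Pattern ranking scalarizes each h-vector token by its mean
  (`scalarize="l2"` gives the norm) and applies a one-vs-rest Wilcoxon
  rank-sum test per type; top 10 patterns are kept.
- The gene graph takes each top pattern's two highest-scoring genes, uses
  their W_j rows as embeddings (a duplicate gene keeps one node with the
  averaged embedding), and connects pairs with cosine similarity > 0.5.
  Centralities: degree, normalized betweenness, eigenvector, pagerank
  (damping 0.85), closeness — "eigenvalue" and "proximity" in the
  literature are read as the nearest standard measures. The Q statistic is
  the mean of the five descending-order ranks (average ranks on ties);
  smaller Q = more central. Graphs are built per cell type.
- Shapley attribution uses the DeepLIFT Rescale chain against the
  background feature mean: linear layers contribute their weights, each
  ReLU the secant slope (act(x) − act(bg)) / (z(x) − z(bg)), falling back
  to the ReLU Jacobian at the background when |z(x) − z(bg)| < 1e-9. For
  linear models this equals the exact Shapley value of the mean-imputation
  value function; on small ReLU nets it rank-agrees with exhaustive
  coalition enumeration (checked in the tests).

### Metrics

Per-class precision/recall/F1 from one-vs-rest confusion counts; macro-F1
over classes present in the truth, with P or R defined as 0 on empty
denominators. ARI and silhouette are delegated to scikit-learn; ASW is
rescaled to [0, 1]. kBET acceptance is the fraction of cells whose k-NN
batch composition passes a chi-square goodness-of-fit test against the
global batch frequencies at α = 0.05 (higher = better mixed; classical kBET
reports the rejection rate). The composite score uses
biology = (MAP + type-ASW + NC)/3, batch = (SAS + omics-ASW + GC)/3,
overall = 0.4·batch + 0.6·biology, with MAP = mean average precision of
same-type retrieval in the k-NN ranking, NC = mean same-type fraction among
k-NN, SAS = Seurat-style alignment score over own-layer neighbour counts,
omics-ASW = 1 − scaled layer silhouette, GC = per-type largest connected
component fraction of the k-NN graph. These names are used inconsistently
across toolkits; the definitions above are this package's interpretations
and are not numerically interchangeable with scIB's. k defaults to
min(50, N/10).

## Synthetic data

The generator plants everything the model is supposed to find. K cell types
draw counts from a negative binomial (mean, dispersion) — variance
mean + mean²/dispersion, the standard scRNA count model — whose log-mean is
base_mean plus a type effect on that type's assigned modules plus a
per-(batch, gene) Gaussian offset. Modules are non-overlapping gene sets
emitted as a GMT; one gene per type gets a 1.5× boosted effect and is
recorded as the planted marker. Batch offsets are additive on the log-mean
scale and independent of type, so they are removable in principle and any
batch-type correlation in a fit is the model's fault. Defaults (1000 genes,
2000 cells, 4 types, 2 batches, 20 modules of 25 genes, type effect 2.0,
batch SD 0.3, dispersion 2.0) produce a dataset a nearest-centroid
classifier already solves — the tests verify learnability before judging
the model.

What the generator does not emulate: library-size heterogeneity, dropout
beyond NB sampling, overlapping or hierarchical programs, rare types
(except via the imbalance subsampler), or batch effects that interact with
type. Passing tests therefore show the machinery is correct and the
objectives move the right quantities — not that performance transfers to
real atlases.

Two corruption harnesses mirror the robustness experiments: `corrupt_labels`
flips exactly round(ratio·N) labels to uniformly drawn wrong classes;
`subsample_imbalance` builds major:minor pairs at ratios like 100:1–500:1.

## Problem sizes

The test suite and `scripts/acceptance.py` use the 2000-cell default above
(three seeds; full, loss-ablated, and 20%-label-noise variants) and a
400-cell fixture for unit tests — sizes chosen so the whole study re-runs
in about a minute on one CPU while keeping every per-type cell count in the
hundreds.

## Known limitations

- The numpy implementation is CPU-only and single-threaded by design;
  atlas-scale training (10⁵+ cells, hundreds of pathways) would want a GPU
  port of the same equations.
- Literal-form L4 is exposed for study but must not be used for training
  (unbounded below, see above).
- Novel cell types absent from the reference are forced into existing
  classes; probabilities are softmax outputs, not calibrated uncertainty.
- kBET uses the chi-square approximation throughout; with very small
  k·frequency the test is conservative.
- Enrichment is over-representation only (hypergeometric + BH); no ranked
  GSEA statistic is computed.
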