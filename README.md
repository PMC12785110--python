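# plkd

Pattern learning and knowledge distillation for single-cell cell-type
annotation.

`plkd` annotates cells in query scRNA-seq datasets from a labelled reference
while simultaneously removing batch effects from the learned cell embedding,
and traces every prediction back to pathways and marker genes. It is aimed at
bioinformaticians who annotate recurring batches of single-cell data: train
once on a curated reference, then annotate arbitrarily many query batches
with a model small enough to run anywhere.

## Model

Two models are trained in sequence.

**Teacher (Transformer).** A *Navigator* module holds m parallel linear maps
W_j ∈ R^{n×h}, one per *pattern* (a gene set with a putative shared
function). An optional knowledge-based mask, built from a GMT pathway file,
zeroes every row of W_j belonging to a gene outside pathway j, so token
v_j = W_jᵀ x can only read its pathway's genes. A learnable cls token c is
appended and a single 2-head scaled-dot-product self-attention layer updates
all tokens; the updated cls position c_r is the cell embedding, and a fully
connected classifier maps it to k class logits. The Teacher minimizes

* **L1, divergence-based clustering loss** — with the minibatch similarity
  kernel s_ij = exp(−‖c_r,i − c_r,j‖²) and per-class assignment columns Y_a,
  L1 = (1/k) Σ_{a<b} (Y_a S Y_bᵀ) / √(Y_a S Y_aᵀ · Y_b S Y_bᵀ). Orthogonal
  class assignments score 0, identical ones (k−1)/2; minimizing it pushes
  clusters apart in embedding space, which is what removes batch structure.
* **L2, cross-entropy** against the reference labels.

**Student (MLP).** A plain n → 256 → 64 → k ReLU network distilled from the
frozen Teacher: it never sees the reference labels, only the Teacher's
temperature-softened class distributions (T = 3), via the tempered KL loss
L3 = mean_i KL(softmax(y_i^teacher/T) ‖ softmax(y_i^student/T)), plus a small
self-entropy term L4 on the batch-mean logits that counteracts the
over-smoothing soft labels induce. At pathway-scale configurations the
Student carries ~2% of the Teacher's parameters.

**Interpretability.** Teacher side: row sums P_j of W_j define each
pattern's gene set (genes above the mean score), annotated by
hypergeometric over-representation against a GMT; a one-vs-rest rank-sum
test on pattern tokens ranks the top-10 patterns per cell type, whose top-2
genes form a gene co-expression graph scored by five centralities and a
rank-consensus Q statistic. Student side: DeepLIFT-style chained-multiplier
Shapley attribution per gene (exact for linear layers). The consensus marker
list is the intersection of both routes, ordered by SHAP rank.

All networks, losses and gradients are implemented directly in numpy — the
models are one attention layer and a small MLP, so explicit backprop keeps
the package light and every gradient finite-difference-checkable.

## Worked example

```python
import numpy as np
from plkd import (SimulationConfig, simulate, normalize_log1p,
                  build_knowledge_mask, TrainConfig,
                  train_teacher, train_student, predict)

ds = simulate(SimulationConfig(seed=1))          # 2000 cells, 4 types, 2 batches
X = normalize_log1p(ds.expression)
mask = build_knowledge_mask(X.gene_names, ds.planted_sets)

teacher, log = train_teacher(X, TrainConfig(seed=1), mask=mask)
student, _ = train_student(X, teacher, TrainConfig(seed=1))

labels, probs = predict(student, X)
print("student accuracy:", np.mean(labels == ds.true_type))
print("final teacher loss:", round(log[-1]["loss"], 4))
```

```
student accuracy: 1.0
final teacher loss: 0.0016
```

The planted 4-type, 2-batch simulation is fully learnable; the Teacher
reaches perfect training accuracy within 6 epochs and the distilled Student
matches it. The same pipeline is available from the shell:

```sh
plkd simulate --seed 1 --out sim/sim.h5ad
plkd train --ref sim/sim.h5ad --gmt sim/sim.gmt --seed 1 --out sim/model.npz
plkd predict --model sim/model.npz --query sim/sim.h5ad --out sim/pred.csv
plkd interpret --model sim/model.npz --query sim/sim.h5ad \
    --gmt sim/sim.gmt --type type_0 --out sim/report
plkd evaluate --emb sim/emb.csv --types t.csv --batches b.csv --out metrics.json
```

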