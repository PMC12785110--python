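"""Classification and batch-integration quality metrics.

Classification: per-class precision/recall/F1 from one-vs-rest confusion
counts, accuracy and macro-F1. Integration: ARI, scaled average silhouette
width, kBET-style acceptance rate, and the composite biology-conservation /
batch-removal / overall score

    biology  = (MAP + celltype_ASW + NC) / 3
    batch    = (SAS + omics_ASW + GC) / 3
    overall  = 0.4 * batch + 0.6 * biology

Component conventions (the names come from the multi-omics integration
literature; exact definitions vary between toolkits, the ones used here are
documented in docs/methods.md): MAP is mean average precision of same-type
retrieval in the k-NN ranking, NC the mean fraction of k-NN sharing the
cell's type, SAS the Seurat alignment score over k-NN own-layer counts, GC
the per-type largest-connected-component fraction of the k-NN graph, and
omics_ASW = 1 - scaled silhouette of the layer labels (higher = better
mixed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _as_labels(a) -> np.ndarray:
    a = np.asarray(a)
    if a.size == 0:
        raise ValueError("empty label vector")
    return a.astype(str)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def classification_metrics(true_labels, pred_labels) -> dict:
    """Accuracy, per-class precision/recall/F1 and macro-F1.

    Macro-F1 averages F1 over the classes present in the true labels. A
    class never predicted (or absent) contributes precision or recall 0.
    """
    t = _as_labels(true_labels)
    p = _as_labels(pred_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    classes = sorted(set(t))
    per_class = {}
    for c in classes:
        tp = int(np.sum((t == c) & (p == c)))
        fp = int(np.sum((t != c) & (p == c)))
        fn = int(np.sum((t == c) & (p != c)))
        tn = int(t.size - tp - fp - fn)
        cc = ConfusionCounts(tp, fp, fn, tn)
        per_class[c] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
                        "precision": cc.precision, "recall": cc.recall,
                        "f1": cc.f1}
    return {
        "accuracy": float(np.mean(t == p)),
        "per_class": per_class,
        "macro_f1": float(np.mean([per_class[c]["f1"] for c in classes])),
    }


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions."""
    from sklearn.metrics import adjusted_rand_score

    a, b = _as_labels(labels_a), _as_labels(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


# ---------------------------------------------------------------------------
# silhouette / kBET
# ---------------------------------------------------------------------------

def asw_scaled(embeddings: np.ndarray, labels) -> float:
    """Scaled average silhouette width ``(mean_silhouette + 1) / 2`` in [0,1]."""
    from sklearn.metrics import silhouette_score

    labels = _as_labels(labels)
    if len(set(labels)) < 2:
        raise ValueError("silhouette needs at least 2 labels")
    s = silhouette_score(np.asarray(embeddings, dtype=np.float64), labels)
    return float((s + 1.0) / 2.0)


def kbet_acceptance(embeddings: np.ndarray, batch_labels,
                    k: int | None = None, alpha: float = 0.05) -> float:
    """kBET-style acceptance rate: fraction of cells whose k-NN batch
    composition passes a chi-square goodness-of-fit test against the global
    batch frequencies at level ``alpha``. Higher = better mixed.
    """
    from scipy.stats import chi2
    from sklearn.neighbors import NearestNeighbors

    E = np.asarray(embeddings, dtype=np.float64)
    b = _as_labels(batch_labels)
    N = E.shape[0]
    batches, codes = np.unique(b, return_inverse=True)
    if batches.size < 2:
        raise ValueError("need at least 2 batches")
    if k is None:
        k = min(50, max(10, N // 10))
    if k >= N:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k).fit(E)
    _, idx = nn.kneighbors(E)
    freqs = np.bincount(codes, minlength=batches.size) / N
    expected = k * freqs
    counts = np.zeros((N, batches.size))
    neigh_codes = codes[idx]
    for j in range(batches.size):
        counts[:, j] = (neigh_codes == j).sum(axis=1)
    stat = ((counts - expected) ** 2 / np.maximum(expected, 1e-12)).sum(axis=1)
    pvals = chi2.sf(stat, df=batches.size - 1)
    return float(np.mean(pvals > alpha))


# ---------------------------------------------------------------------------
# composite integration score
# ---------------------------------------------------------------------------

@dataclass
class CompositeScore:
    map: float
    celltype_asw: float
    nc: float
    sas: float
    omics_asw: float
    gc: float

    @property
    def biology_conservation(self) -> float:
        return (self.map + self.celltype_asw + self.nc) / 3.0

    @property
    def batch_removal(self) -> float:
        return (self.sas + self.omics_asw + self.gc) / 3.0

    @property
    def overall(self) -> float:
        return 0.4 * self.batch_removal + 0.6 * self.biology_conservation

    def as_dict(self) -> dict[str, float]:
        return {"map": self.map, "celltype_asw": self.celltype_asw,
                "nc": self.nc, "sas": self.sas, "omics_asw": self.omics_asw,
                "gc": self.gc,
                "biology_conservation": self.biology_conservation,
                "batch_removal": self.batch_removal, "overall": self.overall}


def _knn_indices(E: np.ndarray, k: int) -> np.ndarray:
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(E)
    _, idx = nn.kneighbors(E)
    return idx[:, 1:]  # drop self


def _mean_average_precision(idx: np.ndarray, codes: np.ndarray) -> float:
    same = codes[idx] == codes[:, None]       # (N, k) ranked by distance
    hits = np.cumsum(same, axis=1)
    ranks = np.arange(1, idx.shape[1] + 1)
    precision_at = hits / ranks
    ap = np.where(same.sum(axis=1) > 0,
                  (precision_at * same).sum(axis=1) / np.maximum(same.sum(axis=1), 1),
                  0.0)
    return float(ap.mean())


def _seurat_alignment(idx: np.ndarray, codes: np.ndarray, n_layers: int) -> float:
    # 1 - (xbar - k/B) / (k - k/B), xbar = mean own-layer neighbour count
    k = idx.shape[1]
    own = (codes[idx] == codes[:, None]).sum(axis=1)
    expected = k / n_layers
    score = 1.0 - (own.mean() - expected) / (k - expected)
    return float(np.clip(score, 0.0, 1.0))


def _graph_connectivity(idx: np.ndarray, codes: np.ndarray) -> float:
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    N, k = idx.shape
    rows = np.repeat(np.arange(N), k)
    A = sp.coo_matrix((np.ones(N * k), (rows, idx.ravel())), shape=(N, N))
    A = A.maximum(A.T).tocsr()
    fracs = []
    for c in np.unique(codes):
        sel = np.nonzero(codes == c)[0]
        if sel.size < 2:
            fracs.append(1.0)
            continue
        sub = A[sel][:, sel]
        n_comp, lab = connected_components(sub, directed=False)
        largest = np.bincount(lab).max()
        fracs.append(largest / sel.size)
    return float(np.mean(fracs))


def composite_score(joint_embeddings: np.ndarray, type_labels, layer_labels,
                    k: int | None = None) -> CompositeScore:
    """Composite integration score over a joint embedding.

    ``layer_labels`` mark the batch/omics layer of each cell; ``type_labels``
    the biological identity. All six components are clipped to [0, 1].
    """
    E = np.asarray(joint_embeddings, dtype=np.float64)
    t = _as_labels(type_labels)
    lay = _as_labels(layer_labels)
    if t.shape[0] != E.shape[0] or lay.shape[0] != E.shape[0]:
        raise ValueError("labels must match the number of cells")
    N = E.shape[0]
    if k is None:
        k = min(50, max(5, N // 10))
    idx = _knn_indices(E, k)
    _, t_codes = np.unique(t, return_inverse=True)
    layers, l_codes = np.unique(lay, return_inverse=True)

    clip = lambda v: float(np.clip(v, 0.0, 1.0))
    map_score = clip(_mean_average_precision(idx, t_codes))
    ct_asw = clip(asw_scaled(E, t))
    nc = clip(float((t_codes[idx] == t_codes[:, None]).mean()))
    if layers.size < 2:
        raise ValueError("need at least 2 layers/batches")
    sas = clip(_seurat_alignment(idx, l_codes, layers.size))
    omics_asw = clip(1.0 - asw_scaled(E, lay))
    gc = clip(_graph_connectivity(idx, t_codes))
    return CompositeScore(map=map_score, celltype_asw=ct_asw, nc=nc,
                          sas=sas, omics_asw=omics_asw, gc=gc)
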