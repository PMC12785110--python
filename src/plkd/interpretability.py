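"""Tracing predictions back to pathways and genes.

Teacher side: each pattern's projection matrix W_j is summarized by its row
sums P_j; genes above the mean of P_j form the pattern's gene set, which is
annotated by hypergeometric over-representation against a GMT collection.
Per-type top patterns come from a one-vs-rest rank-sum test on scalarized
pattern tokens. The top-2 genes of each top pattern contribute their W_j
rows as gene embeddings to a cell-type-specific co-expression graph, scored
by five centrality indicators and aggregated into a rank-consensus Q
statistic.

Student side: a DeepLIFT-style multiplier chain through the plain dense
layers yields per-gene Shapley-value approximations against a mean
background reference; for linear layers the chain is exact. The consensus
gene list intersects the Teacher-derived gene pool with the Student's
SHAP ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import GeneSetCollection
from .student_model import StudentParams
from .teacher_model import TeacherParams


# ---------------------------------------------------------------------------
# Teacher: pattern gene sets and enrichment
# ---------------------------------------------------------------------------

@dataclass
class PatternGeneSet:
    """Genes whose row-sum score in W_j strictly exceeds the mean score."""

    pattern_index: int
    genes: list[str]
    row_scores: np.ndarray
    threshold: float


def extract_pattern_gene_set(W_j: np.ndarray, gene_names: list[str],
                             pattern_index: int = 0) -> PatternGeneSet:
    """Row-sum W_j, threshold at the mean, keep strictly-above genes."""
    P = np.asarray(W_j, dtype=np.float64).sum(axis=1)
    thr = float(P.mean())
    sel = np.nonzero(P > thr)[0]
    if sel.size == 0:
        warnings.warn(f"pattern {pattern_index}: no gene strictly above the mean "
                      "row-sum; empty gene set")
    return PatternGeneSet(
        pattern_index=pattern_index,
        genes=[gene_names[i] for i in sel],
        row_scores=P,
        threshold=thr,
    )


def enrich_gene_set(genes, collection: GeneSetCollection, universe) -> list[dict]:
    """Hypergeometric over-representation of ``genes`` in each pathway.

    p = P(overlap >= observed) drawn from a universe of all model genes;
    Benjamini-Hochberg q-values attached; rows sorted by ascending p.
    """
    from scipy.stats import hypergeom
    from statsmodels.stats.multitest import multipletests

    genes = set(genes)
    universe = set(universe)
    if not genes:
        raise ValueError("empty query gene set")
    if not genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    M, q = len(universe), len(genes)
    rows = []
    for pw in collection.names:
        members = collection[pw] & universe
        overlap = len(genes & members)
        # P(X >= overlap), X ~ Hypergeom(M, |members|, q)
        p = float(hypergeom.sf(overlap - 1, M, len(members), q)) if members else 1.0
        rows.append({"pathway": pw, "overlap": overlap,
                     "pathway_size": len(members), "p_value": min(p, 1.0)})
    if rows:
        _, qvals, _, _ = multipletests([r["p_value"] for r in rows], method="fdr_bh")
        for r, qq in zip(rows, qvals):
            r["q_value"] = float(qq)
    rows.sort(key=lambda r: (r["p_value"], r["pathway"]))
    return rows


def rank_patterns_by_type(tokens: np.ndarray, labels, top: int = 10,
                          scalarize: str = "mean") -> dict[str, list[dict]]:
    """Cell-type-specific top patterns by one-vs-rest Wilcoxon rank-sum.

    ``tokens`` is (cells, m, h); each pattern is reduced to a per-cell scalar
    (mean over the h entries by default, ``scalarize="l2"`` for the norm),
    then scored one type vs the rest. Returns, per type, the ``top`` patterns
    ranked by descending rank-sum statistic. Types with fewer than 3 cells
    are skipped with a warning.
    """
    from scipy.stats import ranksums

    tokens = np.asarray(tokens, dtype=np.float64)
    if scalarize == "mean":
        scores = tokens.mean(axis=2)          # (cells, m)
    elif scalarize == "l2":
        scores = np.linalg.norm(tokens, axis=2)
    else:
        raise ValueError(f"unknown scalarize {scalarize!r}")
    labels = np.asarray(labels).astype(str)
    types = sorted(set(labels))
    if len(types) < 2:
        raise ValueError("need at least 2 types")
    m = scores.shape[1]
    out: dict[str, list[dict]] = {}
    for t in types:
        sel = labels == t
        if sel.sum() < 3:
            warnings.warn(f"type {t!r} has fewer than 3 cells; skipped")
            continue
        stats = []
        for j in range(m):
            res = ranksums(scores[sel, j], scores[~sel, j])
            stats.append({"pattern": j, "statistic": float(res.statistic),
                          "p_value": float(res.pvalue)})
        stats.sort(key=lambda r: -r["statistic"])
        out[t] = stats[:top]
    return out


# ---------------------------------------------------------------------------
# gene co-expression graph and key genes
# ---------------------------------------------------------------------------

@dataclass
class GeneGraph:
    """Genes with embedding vectors, connected above a cosine threshold."""

    genes: list[str]
    embeddings: np.ndarray            # (n_nodes, h)
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i, name in enumerate(self.genes):
            g.add_node(name, embedding=self.embeddings[i])
        for i, j, w in self.edges:
            g.add_edge(self.genes[i], self.genes[j], weight=w)
        return g


def build_gene_graph(teacher: TeacherParams, top_patterns: list[int],
                     gene_names: list[str] | None = None,
                     genes_per_pattern: int = 2,
                     cosine_threshold: float = 0.5) -> GeneGraph:
    """Co-expression graph over the top genes of the top patterns.

    For each listed pattern, its ``genes_per_pattern`` highest row-sum genes
    contribute their W_j rows (length-h vectors) as gene embeddings; 10
    patterns x 2 genes gives up to 20 nodes. A gene chosen by two patterns
    keeps one node with the averaged embedding (with a warning). Undirected
    edges connect pairs with cosine similarity strictly above the threshold.
    """
    if not top_patterns:
        raise ValueError("top_patterns is empty")
    gene_names = teacher.gene_names if gene_names is None else gene_names
    if gene_names is None:
        raise ValueError("gene names are required")
    W = teacher.navigator.effective_weights()
    emb: dict[str, list[np.ndarray]] = {}
    order: list[str] = []
    for j in top_patterns:
        P = W[j].sum(axis=1)
        top_idx = np.argsort(-P)[:genes_per_pattern]
        for g in top_idx:
            name = gene_names[g]
            if name in emb:
                warnings.warn(f"gene {name} selected by multiple patterns; "
                              "embeddings averaged")
            else:
                order.append(name)
            emb.setdefault(name, []).append(W[j][g])
    genes = order
    E = np.stack([np.mean(emb[g], axis=0) for g in genes])
    norms = np.linalg.norm(E, axis=1)
    norms[norms == 0] = 1.0
    U = E / norms[:, None]
    C = U @ U.T
    edges = [(i, j, float(C[i, j]))
             for i in range(len(genes)) for j in range(i + 1, len(genes))
             if C[i, j] > cosine_threshold]
    return GeneGraph(genes=genes, embeddings=E, edges=edges)


def centrality_scores(graph: GeneGraph) -> dict[str, dict[str, float]]:
    """Five indicators per gene: degree, betweenness, eigenvector, pagerank,
    closeness.

    Betweenness is normalized; pagerank uses damping 0.85; closeness is
    computed per connected component. Eigenvector centrality on an edgeless
    or pathological graph falls back to a uniform score.
    """
    import networkx as nx

    g = graph.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=True)
    try:
        eig = nx.eigenvector_centrality_numpy(g) if g.number_of_edges() else \
            {v: 1.0 / g.number_of_nodes() for v in g}
    except Exception:
        eig = {v: 1.0 / g.number_of_nodes() for v in g}
    pr = nx.pagerank(g, alpha=0.85)
    clo = nx.closeness_centrality(g)
    return {v: {"degree": float(deg[v]), "betweenness": float(btw[v]),
                "eigenvector": float(abs(eig[v])), "pagerank": float(pr[v]),
                "closeness": float(clo[v])}
            for v in g}


def q_aggregate(scores: dict[str, dict[str, float]]) -> list[tuple[str, float]]:
    """Rank-consensus Q statistic: mean rank over the five indicators.

    Genes are ranked descending per indicator with average ranks on ties;
    Q(gene) is the mean of its five ranks, so smaller Q = more central.
    Returns (gene, Q) sorted ascending by Q (ties broken by name).
    """
    from scipy.stats import rankdata

    if not scores:
        raise ValueError("no genes to rank")
    genes = list(scores)
    indicators = ["degree", "betweenness", "eigenvector", "pagerank", "closeness"]
    ranks = np.zeros((len(genes), len(indicators)))
    for ji, ind in enumerate(indicators):
        vals = np.array([scores[g][ind] for g in genes])
        ranks[:, ji] = rankdata(-vals, method="average")
    Q = ranks.mean(axis=1)
    out = sorted(zip(genes, Q.tolist()), key=lambda t: (t[1], t[0]))
    return out


# ---------------------------------------------------------------------------
# Student: layer-wise Shapley attribution
# ---------------------------------------------------------------------------

@dataclass
class AttributionResult:
    """Per-cell, per-gene Shapley values for one target class."""

    values: np.ndarray                # (cells, n) or (n,)
    background: np.ndarray            # length-n mean feature vector
    target_class: int
    class_names: list[str] | None = None


def shap_attribution(student: StudentParams, background: np.ndarray,
                     x: np.ndarray, target_class: int) -> np.ndarray:
    """DeepLIFT-style chained-multiplier attribution for the target logit.

    The background reference is the feature-wise mean of the provided
    background set. Each ReLU's multiplier is the secant slope
    ``(act(x) - act(bg)) / (z(x) - z(bg))``; when the denominator is
    (near-)zero the layer's local linear rule at the background (the ReLU
    Jacobian) is used instead. Linear layers contribute their weights, so on
    linear-only networks the chain telescopes and completeness
    ``sum(phi) = f(x) - f(bg)`` is exact; it equals the exact Shapley value
    of the mean-imputation value function for linear models.
    """
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    if background.shape[0] < 1:
        raise ValueError("background must be non-empty")
    bg = background.mean(axis=0)
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = x[None] if single else x

    # forward both x and background, collecting pre-activations
    def fwd(A):
        zs = []
        for l, (W, b) in enumerate(zip(student.weights, student.biases)):
            Z = A @ W + b
            zs.append(Z)
            A = np.maximum(Z, 0.0) if l < student.n_layers - 1 else Z
        return zs

    zx = fwd(X)
    zb = fwd(bg[None])

    # backward multiplier chain, starting from the target logit
    R = np.zeros((X.shape[0], student.k))
    R[:, target_class] = 1.0
    for l in range(student.n_layers - 1, -1, -1):
        if l < student.n_layers - 1:
            dz = zx[l] - zb[l]
            secant = np.where(np.abs(dz) > 1e-9,
                              (np.maximum(zx[l], 0) - np.maximum(zb[l], 0))
                              / np.where(np.abs(dz) > 1e-9, dz, 1.0),
                              (zb[l] > 0).astype(np.float64))
            R = R * secant
        R = R @ student.weights[l].T
    phi = R * (X - bg)
    return phi[0] if single else phi


def attribute_cells(student: StudentParams, background: np.ndarray,
                    X: np.ndarray, target_class: int) -> AttributionResult:
    values = shap_attribution(student, background, X, target_class)
    return AttributionResult(values=np.atleast_2d(values),
                             background=np.atleast_2d(background).mean(axis=0),
                             target_class=target_class,
                             class_names=student.class_names)


def top_shap_genes(attr: AttributionResult, gene_names: list[str],
                   top: int = 10) -> list[tuple[str, float]]:
    """Top genes by mean absolute attribution over the attributed cells."""
    if attr.values.shape[0] == 0:
        raise ValueError("no cells to aggregate")
    mean_abs = np.abs(attr.values).mean(axis=0)
    order = np.argsort(-mean_abs)[:top]
    return [(gene_names[i], float(mean_abs[i])) for i in order]


def consensus_genes(teacher_genes, student_top: list[tuple[str, float]]
                    ) -> list[tuple[str, float]]:
    """Teacher-pool ∩ Student-SHAP list, ordered by the SHAP ranking."""
    teacher_genes = set(teacher_genes)
    out = [(g, v) for g, v in student_top if g in teacher_genes]
    if not out:
        warnings.warn("teacher and student gene lists do not intersect")
    return out
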