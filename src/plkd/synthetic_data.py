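"""Ground-truthed synthetic single-cell datasets.

Generates negative-binomial count matrices with K cell types whose identity
is carried by planted gene modules (pathway-like gene sets), B measurement
batches with additive log-scale offsets, and the matching GMT of planted
modules. Also provides the label-noise corruption and extreme class-imbalance
subsampling harnesses used in robustness experiments.

The count model is NB(mean, dispersion) with variance mean + mean^2/dispersion.
Cell-type signal is additive on the log-mean scale: a gene in one of the
modules assigned to a cell's type has its log-mean raised by ``type_effect``.
Batch offsets are drawn once per (batch, gene) from N(0, batch_shift_sd),
independent of type, so they are removable in principle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import ExpressionMatrix, GeneSetCollection


@dataclass
class SimulationConfig:
    """Parameters of the planted-module count simulator.

    Defaults give a learnable but non-trivial problem: 4 types in 2 batches,
    1000 genes of which 20 modules of 25 genes carry signal, a 2.0 log-fold
    type effect and batch offsets with SD 0.3 on the log-mean scale.
    """

    n_genes: int = 1000
    n_cells: int = 2000
    n_types: int = 4
    n_batches: int = 2
    n_pathways: int = 20
    genes_per_pathway: int = 25
    type_effect: float = 2.0
    batch_shift_sd: float = 0.3
    nb_dispersion: float = 2.0
    base_mean: float = 1.0
    modules_per_type: int = 2
    marker_genes_per_type: int = 1
    marker_effect: float | None = None
    overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells", "n_types", "n_batches",
                     "n_pathways", "genes_per_pathway"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.type_effect < 0:
            raise ValueError("type_effect must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        if not self.overlap and self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ValueError(
                "non-overlapping modules need n_pathways * genes_per_pathway "
                f"<= n_genes ({self.n_pathways}*{self.genes_per_pathway} > {self.n_genes})"
            )


@dataclass
class SyntheticDataset:
    """A simulated dataset plus its ground truth."""

    expression: ExpressionMatrix
    true_type: np.ndarray
    true_batch: np.ndarray
    planted_sets: GeneSetCollection
    type_module_map: dict[str, list[str]]
    marker_genes: dict[str, str] = field(default_factory=dict)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB as Gamma-Poisson: shape=dispersion, scale=mean/dispersion
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam).astype(np.float64)


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Draw a :class:`SyntheticDataset` under ``config`` (reproducible by seed).

    Counts are NB with mean ``base_mean * exp(type activity + batch offset)``.
    Each type activates ``modules_per_type`` modules (round-robin over the
    ``n_pathways`` modules) and, in addition, ``marker_genes_per_type`` genes
    from its first module are boosted by ``marker_effect`` (default
    ``1.5 * type_effect``) to plant an unambiguous per-type marker.
    """
    rng = np.random.default_rng(config.seed)
    G, N, K, B, m = (config.n_genes, config.n_cells, config.n_types,
                     config.n_batches, config.n_pathways)

    gene_names = [f"G{j:05d}" for j in range(G)]
    cell_ids = [f"C{i:05d}" for i in range(N)]

    # planted modules over the gene list
    if config.overlap:
        members = [rng.choice(G, size=config.genes_per_pathway, replace=False)
                   for _ in range(m)]
    else:
        perm = rng.permutation(G)
        members = [perm[j * config.genes_per_pathway:(j + 1) * config.genes_per_pathway]
                   for j in range(m)]
    pathway_names = [f"MODULE_{j:03d}" for j in range(m)]
    planted = GeneSetCollection(
        sets={pathway_names[j]: {gene_names[g] for g in members[j]} for j in range(m)}
    )

    # type -> modules, round-robin so types use disjoint modules when possible
    type_names = [f"type_{t}" for t in range(K)]
    type_module_map: dict[str, list[str]] = {}
    idx = 0
    for t in range(K):
        mods = [(idx + j) % m for j in range(config.modules_per_type)]
        idx += config.modules_per_type
        type_module_map[type_names[t]] = [pathway_names[j] for j in mods]

    # per-type log-activity over genes
    activity = np.zeros((K, G))
    marker_effect = (1.5 * config.type_effect if config.marker_effect is None
                     else config.marker_effect)
    marker_genes: dict[str, str] = {}
    for t, tname in enumerate(type_names):
        for pw in type_module_map[tname]:
            j = pathway_names.index(pw)
            activity[t, members[j]] += config.type_effect
        first = pathway_names.index(type_module_map[tname][0])
        mg = members[first][: config.marker_genes_per_type]
        activity[t, mg] += marker_effect - config.type_effect
        if len(mg):
            marker_genes[tname] = gene_names[int(mg[0])]

    batch_offsets = rng.normal(0.0, config.batch_shift_sd, size=(B, G))
    true_type = rng.integers(0, K, size=N)
    true_batch = rng.integers(0, B, size=N)

    mean = config.base_mean * np.exp(activity[true_type] + batch_offsets[true_batch])
    counts = _nb_sample(rng, mean, config.nb_dispersion)

    type_labels = np.array([type_names[t] for t in true_type])
    batch_labels = np.array([f"batch_{b}" for b in true_batch])
    expr = ExpressionMatrix(
        values=counts,
        gene_names=gene_names,
        cell_ids=cell_ids,
        cell_type=type_labels,
        batch=batch_labels,
    )
    return SyntheticDataset(
        expression=expr,
        true_type=type_labels,
        true_batch=batch_labels,
        planted_sets=planted,
        type_module_map=type_module_map,
        marker_genes=marker_genes,
    )


def corrupt_labels(labels: Sequence[str], noise_ratio: float, seed: int) -> np.ndarray:
    """Reassign exactly ``round(noise_ratio * N)`` labels to a different class.

    Corrupted positions are chosen without replacement; each corrupted cell
    receives a uniformly chosen label different from its original one.
    """
    if not 0.0 <= noise_ratio <= 1.0:
        raise ValueError("noise_ratio must be in [0, 1]")
    labels = np.asarray(labels).copy()
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 distinct labels to corrupt")
    rng = np.random.default_rng(seed)
    n_flip = int(round(noise_ratio * labels.size))
    pos = rng.choice(labels.size, size=n_flip, replace=False)
    for i in pos:
        others = classes[classes != labels[i]]
        labels[i] = rng.choice(others)
    return labels


def subsample_imbalance(labels: Sequence[str], major: str, minor: str,
                        ratio: float, seed: int) -> np.ndarray:
    """Indices of a two-class subsample at a ``major:minor = ratio:1`` imbalance.

    Keeps every majority cell and ``floor(majority_count / ratio)`` minority
    cells (capped at the available count); all other classes are dropped.
    Returns row indices into ``labels``.
    """
    labels = np.asarray(labels)
    maj_idx = np.nonzero(labels == major)[0]
    min_idx = np.nonzero(labels == minor)[0]
    if maj_idx.size == 0 or min_idx.size == 0:
        raise ValueError("both major and minor labels must be present")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    n_minor = min(int(maj_idx.size // ratio), min_idx.size)
    if n_minor == 0:
        raise ValueError(f"ratio {ratio} leaves no minority cells")
    rng = np.random.default_rng(seed)
    keep_minor = rng.choice(min_idx, size=n_minor, replace=False)
    return np.sort(np.concatenate([maj_idx, keep_minor]))
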