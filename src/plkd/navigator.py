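"""Knowledge-based mask and the Navigator pattern projections.

The Navigator maps a cell's length-n expression vector into m pattern tokens
of width h via m parallel linear maps W_j (n x h). A binary gene x pathway
mask derived from a GMT file zeroes the rows of W_j belonging to genes
outside pathway j, so each token can only read its pathway's genes.

In ``persistent`` mask mode (default) the mask is applied multiplicatively in
every forward pass — masked weights stay exactly 0 through any number of
gradient updates, which the downstream interpretability steps rely on. The
``init_only`` mode applies the mask only at initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import GeneSetCollection


@dataclass
class KnowledgeMask:
    """Binary gene x pathway membership matrix."""

    mask: np.ndarray  # (n_genes, m) of {0,1}
    gene_names: list[str]
    pathway_names: list[str]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.float64)
        if self.mask.shape != (len(self.gene_names), len(self.pathway_names)):
            raise ValueError("mask shape does not match gene/pathway name lists")
        if not np.isin(self.mask, (0.0, 1.0)).all():
            raise ValueError("mask entries must be 0 or 1")

    @property
    def m(self) -> int:
        return self.mask.shape[1]

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.mask.astype(int), index=self.gene_names,
                     columns=self.pathway_names).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "KnowledgeMask":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(mask=df.to_numpy(dtype=np.float64),
                   gene_names=[str(g) for g in df.index],
                   pathway_names=[str(p) for p in df.columns])


def build_knowledge_mask(gene_names: Sequence[str],
                         sets: GeneSetCollection) -> KnowledgeMask:
    """``mask[g, j] = 1`` iff gene g belongs to pathway j.

    Pathways with no gene in ``gene_names`` are retained as all-zero columns
    (with a warning) so pattern indices stay aligned with the GMT order.
    """
    gene_names = list(gene_names)
    if not gene_names:
        raise ValueError("gene_names is empty")
    pathway_names = sets.names
    mask = np.zeros((len(gene_names), len(pathway_names)))
    index = {g: i for i, g in enumerate(gene_names)}
    empty = []
    for j, pw in enumerate(pathway_names):
        hit = False
        for g in sets[pw]:
            i = index.get(g)
            if i is not None:
                mask[i, j] = 1.0
                hit = True
        if not hit:
            empty.append(pw)
    if empty:
        warnings.warn(
            f"{len(empty)} pathways share no genes with the gene list "
            f"(all-zero mask columns): {', '.join(empty[:5])}"
        )
    return KnowledgeMask(mask=mask, gene_names=gene_names,
                         pathway_names=pathway_names)


@dataclass
class NavigatorParams:
    """m parallel projection matrices, stored as one (m, n, h) array."""

    W: np.ndarray  # (m, n, h)
    mask: KnowledgeMask | None = None
    mask_mode: str = "persistent"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 3:
            raise ValueError("W must have shape (m, n, h)")
        if self.mask_mode not in ("persistent", "init_only"):
            raise ValueError(f"unknown mask_mode {self.mask_mode!r}")
        if self.mask is not None and self.mask.mask.shape != (self.n, self.m):
            raise ValueError("mask shape does not match W")

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return self.W.shape[1]

    @property
    def h(self) -> int:
        return self.W.shape[2]

    def effective_weights(self) -> np.ndarray:
        """(m, n, h) weights with the persistent mask applied."""
        if self.mask is not None and self.mask_mode == "persistent":
            return self.W * self.mask.mask.T[:, :, None]
        return self.W

    def apply_mask(self) -> None:
        """Zero masked entries of W in place (used after optimizer updates)."""
        if self.mask is not None and self.mask_mode == "persistent":
            self.W *= self.mask.mask.T[:, :, None]


def init_navigator(n: int, h: int, m: int | None = None,
                   mask: KnowledgeMask | None = None,
                   mask_mode: str = "persistent",
                   rng: np.random.Generator | None = None) -> NavigatorParams:
    """Kaiming-uniform init with fan-in counted over unmasked rows only.

    A pattern restricted to a 25-gene pathway sees fan-in 25, not n, so its
    token scale matches that of dense patterns.
    """
    rng = np.random.default_rng() if rng is None else rng
    if mask is not None:
        m = mask.m
    if m is None:
        raise ValueError("m is required when no mask is given")
    W = np.empty((m, n, h))
    for j in range(m):
        fan_in = n if mask is None else max(int(mask.mask[:, j].sum()), 1)
        bound = np.sqrt(6.0 / fan_in)
        W[j] = rng.uniform(-bound, bound, size=(n, h))
    params = NavigatorParams(W=W, mask=mask, mask_mode=mask_mode)
    params.apply_mask()
    if mask is not None and mask_mode == "init_only":
        params.W *= mask.mask.T[:, :, None]
    return params


def navigator_forward(x: np.ndarray, params: NavigatorParams) -> np.ndarray:
    """Project expression into pattern tokens.

    ``x`` may be a single length-n vector or a (batch, n) matrix; the output
    is (m, h) or (batch, m, h) accordingly, with token j = (W_j ⊙ mask_j)^T x.
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != params.n:
        raise ValueError(f"expected {params.n} genes, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite expression input")
    W = params.effective_weights()
    m, n, h = W.shape
    # one gemm over a (n, m*h) view is much faster than the 3-D einsum
    W2 = np.ascontiguousarray(W.transpose(1, 0, 2)).reshape(n, m * h)
    tokens = (X @ W2).reshape(X.shape[0], m, h)
    return tokens[0] if single else tokens


def navigator_backward(X: np.ndarray, params: NavigatorParams,
                       d_tokens: np.ndarray) -> np.ndarray:
    """Gradient of a scalar loss w.r.t. W given d(tokens), (batch, m, h).

    The persistent mask is applied to the gradient so masked entries never
    receive updates.
    """
    m, n, h = params.W.shape
    dW2 = X.T @ d_tokens.reshape(X.shape[0], m * h)      # (n, m*h)
    dW = np.ascontiguousarray(dW2.reshape(n, m, h).transpose(1, 0, 2))
    if params.mask is not None and params.mask_mode == "persistent":
        dW *= params.mask.mask.T[:, :, None]
    return dW
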