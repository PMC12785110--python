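"""The lightweight Student: a plain MLP from gene expression to class logits.

Default layout n -> 256 -> 64 -> k with ReLU, no dropout or batch norm —
the layer-wise attribution in :mod:`plkd.interpretability` assumes plain
dense layers. At pathway-scale Teacher configurations this Student carries
roughly 2% of the Teacher's parameters, which is what makes distilled
inference on large query sets cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class StudentParams:
    """Ordered dense layers (weights W_l: in x out, biases b_l)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "relu"
    gene_names: list[str] | None = None
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must pair up")
        for l in range(len(self.weights) - 1):
            if self.weights[l].shape[1] != self.weights[l + 1].shape[0]:
                raise ValueError(f"layer {l} output does not feed layer {l + 1}")
        if self.activation != "relu":
            raise ValueError("only relu is supported")

    @property
    def n(self) -> int:
        return self.weights[0].shape[0]

    @property
    def k(self) -> int:
        return self.weights[-1].shape[1]

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def param_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            out[f"W{l}"] = W
            out[f"b{l}"] = b
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.param_dict().values()))


def init_student(n_genes: int, n_classes: int,
                 hidden: tuple[int, ...] = (256, 64), seed: int = 0,
                 gene_names: list[str] | None = None,
                 class_names: list[str] | None = None) -> StudentParams:
    rng = np.random.default_rng(seed)
    sizes = [n_genes, *hidden, n_classes]
    weights, biases = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(6.0 / a)  # Kaiming-uniform, fan-in
        weights.append(rng.uniform(-bound, bound, size=(a, b)))
        biases.append(np.zeros(b))
    return StudentParams(weights=weights, biases=biases,
                         gene_names=gene_names, class_names=class_names)


def student_forward(x: np.ndarray, params: StudentParams,
                    return_cache: bool = False):
    """MLP forward pass. ``x`` is a length-n vector or (batch, n) matrix."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    A = x[None] if single else x
    if A.shape[1] != params.n:
        raise ValueError(f"expected {params.n} genes, got {A.shape[1]}")
    cache = []
    for l, (W, b) in enumerate(zip(params.weights, params.biases)):
        Z = A @ W + b
        cache.append({"a": A, "z": Z})
        A = np.maximum(Z, 0.0) if l < params.n_layers - 1 else Z
    logits = A
    out = logits[0] if single else logits
    return (out, cache) if return_cache else out


def student_backward(params: StudentParams, cache: list[dict],
                     d_logits: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients w.r.t. all Student parameters given d(logits)."""
    grads: dict[str, np.ndarray] = {}
    da = np.asarray(d_logits, dtype=np.float64)
    for l in range(params.n_layers - 1, -1, -1):
        c = cache[l]
        if l < params.n_layers - 1:
            da = da * (c["z"] > 0)
        grads[f"W{l}"] = c["a"].T @ da
        grads[f"b{l}"] = da.sum(axis=0)
        da = da @ params.weights[l].T
    return grads
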