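"""The Teacher: pattern tokens + cls token -> 1-layer, 2-head self-attention
-> classifier.

The Navigator's m pattern tokens are concatenated with a learnable cls token;
a single self-attention layer (2 heads, scaled dot-product) updates all
tokens; the updated cls position c_r is the cell embedding, and a fully
connected classifier maps it to k class logits.

Forward and backward passes are written directly in numpy: the model is one
attention layer over a few dozen tokens, so explicit backprop is simple and
keeps the package dependency-light. All parameter arrays live in
:class:`TeacherParams` and are updated in place by the trainer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .navigator import KnowledgeMask, NavigatorParams, init_navigator, navigator_backward, navigator_forward


@dataclass
class TeacherConfig:
    """Architecture hyperparameters.

    h is the token width, m the number of patterns (in knowledge mode m is
    taken from the GMT), heads the attention head count. The classifier is a
    single linear layer h -> k by default; ``classifier_hidden`` inserts one
    ReLU hidden layer. ``transformer_extras`` adds the standard residual +
    layer-norm around the attention layer (off by default: the core model is
    plain attention).
    """

    h: int = 48
    m: int = 64
    heads: int = 2
    classifier_hidden: int | None = None
    transformer_extras: bool = False
    mask_mode: str = "persistent"

    def __post_init__(self) -> None:
        if self.h % self.heads != 0:
            raise ValueError("h must be divisible by the head count")


@dataclass
class TeacherParams:
    """All learnable parameters of the Teacher."""

    navigator: NavigatorParams
    cls_token: np.ndarray            # (h,)
    Wq: np.ndarray                   # (h, h) shared projections
    Wk: np.ndarray
    Wv: np.ndarray
    Whq: np.ndarray                  # (heads, h, d) per-head projections
    Whk: np.ndarray
    Whv: np.ndarray
    Wo: np.ndarray                   # (h, h)
    cls_W: list[np.ndarray]          # classifier weights
    cls_b: list[np.ndarray]
    ln_gamma: np.ndarray | None = None
    ln_beta: np.ndarray | None = None
    config: TeacherConfig = field(default_factory=TeacherConfig)
    gene_names: list[str] | None = None
    class_names: list[str] | None = None

    @property
    def h(self) -> int:
        return self.cls_token.shape[0]

    @property
    def k(self) -> int:
        return self.cls_b[-1].shape[0]

    @property
    def d_head(self) -> int:
        return self.h // self.config.heads

    def param_dict(self) -> dict[str, np.ndarray]:
        out = {
            "navigator.W": self.navigator.W,
            "cls_token": self.cls_token,
            "Wq": self.Wq, "Wk": self.Wk, "Wv": self.Wv,
            "Whq": self.Whq, "Whk": self.Whk, "Whv": self.Whv,
            "Wo": self.Wo,
        }
        for i, (W, b) in enumerate(zip(self.cls_W, self.cls_b)):
            out[f"cls_W{i}"] = W
            out[f"cls_b{i}"] = b
        if self.ln_gamma is not None:
            out["ln_gamma"] = self.ln_gamma
            out["ln_beta"] = self.ln_beta
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.param_dict().values()))


def init_teacher(n_genes: int, n_classes: int, config: TeacherConfig | None = None,
                 mask: KnowledgeMask | None = None, seed: int = 0,
                 gene_names: list[str] | None = None,
                 class_names: list[str] | None = None) -> TeacherParams:
    """Random initialization (Xavier-uniform for attention and classifier)."""
    config = TeacherConfig() if config is None else config
    rng = np.random.default_rng(seed)
    h, heads = config.h, config.heads
    d = h // heads
    nav = init_navigator(n_genes, h, m=config.m, mask=mask,
                         mask_mode=config.mask_mode, rng=rng)

    def xavier(shape):
        bound = np.sqrt(6.0 / (shape[-2] + shape[-1]))
        return rng.uniform(-bound, bound, size=shape)

    sizes = ([h, n_classes] if config.classifier_hidden is None
             else [h, config.classifier_hidden, n_classes])
    cls_W = [xavier((a, b)) for a, b in zip(sizes[:-1], sizes[1:])]
    cls_b = [np.zeros(b) for b in sizes[1:]]
    ln_gamma = np.ones(h) if config.transformer_extras else None
    ln_beta = np.zeros(h) if config.transformer_extras else None
    return TeacherParams(
        navigator=nav,
        cls_token=rng.normal(0.0, 0.02, size=h),
        Wq=xavier((h, h)), Wk=xavier((h, h)), Wv=xavier((h, h)),
        Whq=xavier((heads, h, d)), Whk=xavier((heads, h, d)), Whv=xavier((heads, h, d)),
        Wo=xavier((h, h)),
        cls_W=cls_W, cls_b=cls_b,
        ln_gamma=ln_gamma, ln_beta=ln_beta,
        config=config, gene_names=gene_names, class_names=class_names,
    )


# ---------------------------------------------------------------------------
# forward
# ---------------------------------------------------------------------------

def _softmax_rows(s: np.ndarray) -> np.ndarray:
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def self_attention_layer(tokens: np.ndarray, params: TeacherParams,
                         return_cache: bool = False):
    """Apply the single multi-head self-attention layer.

    ``tokens`` is (batch, M, h) with M = m + 1 (patterns plus cls). Per head,
    ``Attn = softmax(Q K^T / sqrt(d_head)) V``; heads are concatenated and
    mixed by W_O. With ``transformer_extras`` a residual connection and layer
    norm wrap the attention output.
    """
    I = np.asarray(tokens, dtype=np.float64)
    if not np.all(np.isfinite(I)):
        raise ValueError("non-finite attention input")
    single = I.ndim == 2
    if single:
        I = I[None]
    d = params.d_head
    scale = 1.0 / np.sqrt(d)
    Q = I @ params.Wq
    K = I @ params.Wk
    V = I @ params.Wv
    Qh = np.einsum("bmh,ihd->bimd", Q, params.Whq)   # (B, heads, M, d)
    Kh = np.einsum("bmh,ihd->bimd", K, params.Whk)
    Vh = np.einsum("bmh,ihd->bimd", V, params.Whv)
    scores = np.einsum("bimd,bind->bimn", Qh, Kh) * scale
    A = _softmax_rows(scores)                        # rows sum to 1
    H = np.einsum("bimn,bind->bimd", A, Vh)          # (B, heads, M, d)
    B, _, M, _ = H.shape
    concatH = H.transpose(0, 2, 1, 3).reshape(B, M, params.h)
    O = concatH @ params.Wo
    cache = {"I": I, "Q": Q, "K": K, "V": V, "Qh": Qh, "Kh": Kh, "Vh": Vh,
             "A": A, "concatH": concatH, "attn_out": O}
    if params.config.transformer_extras:
        res = I + O
        mu = res.mean(axis=-1, keepdims=True)
        var = res.var(axis=-1, keepdims=True)
        xhat = (res - mu) / np.sqrt(var + 1e-5)
        O = xhat * params.ln_gamma + params.ln_beta
        cache.update({"res": res, "xhat": xhat, "var": var})
    cache["O"] = O
    out = O[0] if single else O
    return (out, cache) if return_cache else out


def teacher_forward(x: np.ndarray, params: TeacherParams,
                    return_cache: bool = False):
    """Full Teacher pass: expression -> (embedding, updated tokens, logits).

    Returns a dict with keys ``embedding`` (B, h), ``tokens`` (B, m, h: the
    updated pattern tokens r_j), ``pattern_tokens`` (the pre-attention v_j)
    and ``logits`` (B, k). A single vector input returns unbatched arrays.
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = x[None] if single else x
    v = navigator_forward(X, params.navigator)               # (B, m, h)
    Bn = X.shape[0]
    cls = np.broadcast_to(params.cls_token, (Bn, 1, params.h))
    I = np.concatenate([v, cls], axis=1)                     # cls last
    O, att_cache = self_attention_layer(I, params, return_cache=True)
    emb = O[:, -1, :]
    r = O[:, :-1, :]
    a = emb
    cls_cache = []
    for li, (W, b) in enumerate(zip(params.cls_W, params.cls_b)):
        z = a @ W + b
        if li < len(params.cls_W) - 1:
            a_next = np.maximum(z, 0.0)
        else:
            a_next = z
        cls_cache.append({"a": a, "z": z})
        a = a_next
    logits = a
    out = {
        "embedding": emb[0] if single else emb,
        "tokens": r[0] if single else r,
        "pattern_tokens": v[0] if single else v,
        "logits": logits[0] if single else logits,
    }
    if return_cache:
        cache = {"X": X, "v": v, "I": I, "att": att_cache,
                 "emb": emb, "cls": cls_cache}
        return out, cache
    return out


# ---------------------------------------------------------------------------
# backward
# ---------------------------------------------------------------------------

def teacher_backward(params: TeacherParams, cache: Mapping,
                     d_logits: np.ndarray,
                     d_embedding: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. every Teacher parameter.

    ``d_logits`` is (B, k); ``d_embedding`` (B, h) carries any loss applied
    directly to the cell embedding (the clustering loss). Returns a dict
    keyed like :meth:`TeacherParams.param_dict`.
    """
    grads: dict[str, np.ndarray] = {}

    # classifier
    da = np.asarray(d_logits, dtype=np.float64)
    for li in range(len(params.cls_W) - 1, -1, -1):
        c = cache["cls"][li]
        if li < len(params.cls_W) - 1:
            da = da * (c["z"] > 0)
        grads[f"cls_W{li}"] = c["a"].T @ da
        grads[f"cls_b{li}"] = da.sum(axis=0)
        da = da @ params.cls_W[li].T
    d_emb = da
    if d_embedding is not None:
        d_emb = d_emb + d_embedding

    att = cache["att"]
    Bn, M, h = att["I"].shape
    dO = np.zeros((Bn, M, h))
    dO[:, -1, :] = d_emb

    dI_extra = np.zeros((Bn, M, h))
    if params.config.transformer_extras:
        xhat, var, res = att["xhat"], att["var"], att["res"]
        grads["ln_gamma"] = (dO * xhat).sum(axis=(0, 1))
        grads["ln_beta"] = dO.sum(axis=(0, 1))
        dxhat = dO * params.ln_gamma
        inv = 1.0 / np.sqrt(var + 1e-5)
        dres = inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                      - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))
        dI_extra = dres
        dO = dres  # gradient into the attention output (residual passes dres to I too)

    concatH, A, Qh, Kh, Vh = att["concatH"], att["A"], att["Qh"], att["Kh"], att["Vh"]
    grads["Wo"] = np.einsum("bmh,bmo->ho", concatH, dO)
    dconcat = dO @ params.Wo.T
    heads, d = params.config.heads, params.d_head
    dH = dconcat.reshape(Bn, M, heads, d).transpose(0, 2, 1, 3)

    dA = np.einsum("bimd,bind->bimn", dH, Vh)
    dVh = np.einsum("bimn,bimd->bind", A, dH)
    ds = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    scale = 1.0 / np.sqrt(d)
    dQh = np.einsum("bimn,bind->bimd", ds, Kh) * scale
    dKh = np.einsum("bimn,bimd->bind", ds, Qh) * scale

    Q, K, V, I = att["Q"], att["K"], att["V"], att["I"]
    grads["Whq"] = np.einsum("bmh,bimd->ihd", Q, dQh)
    grads["Whk"] = np.einsum("bmh,bimd->ihd", K, dKh)
    grads["Whv"] = np.einsum("bmh,bimd->ihd", V, dVh)
    dQ = np.einsum("bimd,ihd->bmh", dQh, params.Whq)
    dK = np.einsum("bimd,ihd->bmh", dKh, params.Whk)
    dV = np.einsum("bimd,ihd->bmh", dVh, params.Whv)
    grads["Wq"] = np.einsum("bmh,bmo->ho", I, dQ)
    grads["Wk"] = np.einsum("bmh,bmo->ho", I, dK)
    grads["Wv"] = np.einsum("bmh,bmo->ho", I, dV)
    dI = dQ @ params.Wq.T + dK @ params.Wk.T + dV @ params.Wv.T
    if params.config.transformer_extras:
        dI = dI + dI_extra

    grads["cls_token"] = dI[:, -1, :].sum(axis=0)
    d_tokens = dI[:, :-1, :]
    grads["navigator.W"] = navigator_backward(cache["X"], params.navigator, d_tokens)
    return grads
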