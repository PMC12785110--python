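"""Training objectives.

Four losses drive the two models:

* L1 — divergence-based clustering loss: penalizes similarity-weighted
  correlation between the per-class soft-assignment columns of a minibatch,
  pushing clusters apart in embedding space. The pairwise terms are
  normalized by sqrt of the within-class terms (cosine form), so orthogonal
  assignments score 0 and identical assignments score 1 per pair.
* L2 — cross-entropy against one-hot reference labels.
* L3 — temperature-scaled knowledge distillation: mean KL divergence from
  the Teacher's tempered class distribution to the Student's, temperature
  T = 3 by default.
* L4 — self-entropy of the batch-mean Student logits, counteracting the
  over-smoothing that soft-label training induces.

Every loss returns its analytic gradient with respect to its differentiable
inputs; gradients are verified against central finite differences in the
test suite. The cell-similarity kernel s_ij = exp(-||c_i - c_j||^2) is
computed per minibatch.
"""

from __future__ import annotations

import warnings

import numpy as np

_EPS = 1e-12


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# similarity kernel
# ---------------------------------------------------------------------------

def similarity_matrix(embeddings: np.ndarray, squared: bool = True) -> np.ndarray:
    """Gaussian cell-similarity kernel ``s_ij = exp(-dist(c_i, c_j))``.

    ``squared=True`` (default) uses squared Euclidean distance (bandwidth-1
    Gaussian kernel); ``squared=False`` uses the plain Euclidean norm. The
    result is symmetric with a unit diagonal.
    """
    C = np.asarray(embeddings, dtype=np.float64)
    if not np.all(np.isfinite(C)):
        raise ValueError("non-finite embeddings")
    sq = np.sum(C * C, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (C @ C.T)
    np.maximum(d2, 0.0, out=d2)
    dist = d2 if squared else np.sqrt(d2 + _EPS)
    S = np.exp(-dist)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    return S


def similarity_backward(embeddings: np.ndarray, S: np.ndarray,
                        dS: np.ndarray) -> np.ndarray:
    """Gradient of a scalar loss through the squared-Euclidean kernel.

    Given dL/dS, returns dL/d(embeddings). Diagonal entries are constant 1
    and carry no gradient.
    """
    C = np.asarray(embeddings, dtype=np.float64)
    dSym = 0.5 * (dS + dS.T)
    np.fill_diagonal(dSym, 0.0)
    # s = exp(-d2) => dL/d(d2)_ij = -s_ij * dSym_ij
    G = -dSym * S
    # d2_ij = |c_i|^2 + |c_j|^2 - 2 c_i.c_j
    row = G.sum(axis=1)
    return 4.0 * (row[:, None] * C - G @ C)


# ---------------------------------------------------------------------------
# L1: divergence-based clustering loss
# ---------------------------------------------------------------------------

def clustering_divergence_loss(Y: np.ndarray, S: np.ndarray,
                               raw_denominator: bool = False,
                               return_grads: bool = False):
    """Divergence-based clustering loss over class-assignment columns.

    ``Y`` is (N, k): column a holds the soft assignment of every cell to
    class a. With C = Y^T S Y, the loss is
    ``(1/k) * sum_{a<b} C_ab / sqrt(C_aa * C_bb)`` (cosine-normalized;
    ``raw_denominator=True`` uses the literal product ``C_aa * C_bb``).
    Returns the scalar, or ``(loss, dY, dS)`` when ``return_grads``.
    """
    Y = np.asarray(Y, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    N, k = Y.shape
    if k < 2:
        raise ValueError("need at least 2 classes")
    SY = S @ Y
    C = Y.T @ SY                       # (k, k)
    diag = np.diag(C).copy()
    if np.any(diag <= _EPS):
        warnings.warn("class with (near-)zero soft assignment; epsilon guard applied")
        diag = np.maximum(diag, _EPS)

    G = np.zeros((k, k))               # dL/dC
    loss = 0.0
    for a in range(k):
        for b in range(a + 1, k):
            if raw_denominator:
                den = diag[a] * diag[b]
                loss += C[a, b] / den
                G[a, b] += 1.0 / den
                G[a, a] += -C[a, b] / (den * diag[a])
                G[b, b] += -C[a, b] / (den * diag[b])
            else:
                den = np.sqrt(diag[a] * diag[b])
                loss += C[a, b] / den
                G[a, b] += 1.0 / den
                G[a, a] += -0.5 * C[a, b] / (den * diag[a])
                G[b, b] += -0.5 * C[a, b] / (den * diag[b])
    loss /= k
    if not return_grads:
        return loss
    G /= k
    Gs = G + G.T
    dY = SY @ Gs                       # S symmetric
    dS = Y @ G @ Y.T
    return loss, dY, dS


# ---------------------------------------------------------------------------
# L2: cross-entropy
# ---------------------------------------------------------------------------

def cross_entropy_loss(logits: np.ndarray, onehot: np.ndarray,
                       return_grads: bool = False):
    """Mean cross-entropy ``-(1/N) sum_i g_i^T log softmax(y_i)``."""
    logits = np.asarray(logits, dtype=np.float64)
    onehot = np.asarray(onehot, dtype=np.float64)
    if logits.shape != onehot.shape:
        raise ValueError("logits and onehot shapes differ")
    if not np.allclose(onehot.sum(axis=1), 1.0):
        raise ValueError("onehot rows must sum to 1")
    N = logits.shape[0]
    P = _softmax(logits)
    loss = -np.sum(onehot * np.log(np.maximum(P, _EPS))) / N
    if not return_grads:
        return loss
    dlogits = (P - onehot) / N
    return loss, dlogits


def onehot_encode(labels, class_names: list) -> np.ndarray:
    """Encode labels as one-hot rows in the order of ``class_names``."""
    index = {c: i for i, c in enumerate(class_names)}
    out = np.zeros((len(labels), len(class_names)))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"label {lab!r} not among classes {class_names}")
        out[i, index[lab]] = 1.0
    return out


# ---------------------------------------------------------------------------
# L3: distillation
# ---------------------------------------------------------------------------

def distillation_loss(student_logits: np.ndarray, teacher_logits: np.ndarray,
                      T: float = 3.0, return_grads: bool = False):
    """Tempered KL(teacher || student), averaged over cells.

    Teacher logits are treated as constants: the gradient is returned only
    for the Student logits, ``(q - p) / (N * T)`` with p, q the tempered
    teacher/student distributions.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    s = np.asarray(student_logits, dtype=np.float64)
    t = np.asarray(teacher_logits, dtype=np.float64)
    if s.shape != t.shape:
        raise ValueError("student and teacher logits shapes differ")
    N = s.shape[0]
    p = _softmax(t / T)
    q = _softmax(s / T)
    loss = float(np.sum(p * (np.log(p + _EPS) - np.log(q + _EPS))) / N)
    if not return_grads:
        return loss
    d_student = (q - p) / (N * T)
    return loss, d_student


# ---------------------------------------------------------------------------
# L4: self-entropy
# ---------------------------------------------------------------------------

def self_entropy_loss(student_logits: np.ndarray, mode: str = "literal",
                      return_grads: bool = False):
    """Self-entropy of the batch-mean Student logits.

    With ``y = mean_i(student_logits)`` and ``pbar = softmax(y)``:

    * ``literal`` (default): ``L4 = -(1/k) sum_a y[a] * log pbar[a]``
    * ``shannon``: ``L4 = -sum_a pbar[a] * log pbar[a]`` (plain entropy)
    """
    Yl = np.asarray(student_logits, dtype=np.float64)
    if Yl.ndim != 2 or Yl.shape[0] < 1:
        raise ValueError("student_logits must be (N, k) with N >= 1")
    N, k = Yl.shape
    y = Yl.mean(axis=0)
    p = _softmax(y)
    logp = np.log(p + _EPS)
    if mode == "literal":
        loss = float(-(y * logp).sum() / k)
        if not return_grads:
            return loss
        # d/dy_b: -(1/k)[log p_b + y_b - p_b * sum(y)]
        dy = -(logp + y - p * y.sum()) / k
    elif mode == "shannon":
        loss = float(-(p * logp).sum())
        if not return_grads:
            return loss
        # dH/dy_b = p_b * (-H - log p_b) with H = -(p*logp).sum()
        dy = p * ((p * logp).sum() - logp)
    else:
        raise ValueError(f"unknown self_entropy mode {mode!r}")
    dlogits = np.broadcast_to(dy / N, Yl.shape).copy()
    return loss, dlogits
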