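"""Two-stage optimization: Teacher first, then Student distilled from the
frozen Teacher.

The Teacher minimizes lambda1*L1 + lambda2*L2 (clustering + cross-entropy) by
minibatch SGD with momentum and cosine learning-rate decay; training
converges within a handful of epochs (default 6). The Student then minimizes
lambda3*L3 + lambda4*L4 against the frozen Teacher's logits — reference
labels are never shown to the Student, its training target is the Teacher's
tempered soft labels.

All randomness (initialization, shuffling) flows from a single seed and runs
single-threaded, so identical configs reproduce bitwise-identical loss logs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import objectives as ob
from .data_io import ExpressionMatrix
from .navigator import KnowledgeMask
from .student_model import StudentParams, init_student, student_backward, student_forward
from .teacher_model import (TeacherConfig, TeacherParams, init_teacher,
                            teacher_backward, teacher_forward)


@dataclass
class TrainConfig:
    """Optimization settings shared by both stages."""

    epochs: int = 6
    batch_size: int = 256
    lr: float = 0.02
    momentum: float = 0.9
    seed: int = 0
    lambda1: float = 1.0   # clustering loss (Teacher)
    lambda2: float = 1.0   # cross-entropy (Teacher)
    lambda3: float = 1.0   # distillation KL (Student)
    lambda4: float = 0.1   # self-entropy (Student); 1.0 collapses classes
    temperature: float = 3.0
    distill_rescale: bool = True  # multiply the KL gradient by T^2 (standard)
    student_lr: float = 0.05  # the plain MLP tolerates a larger step than the Teacher
    student_hidden: tuple[int, ...] = (256, 64)
    grad_clip: float | None = 5.0  # global-norm gradient clipping
    use_hard_labels: bool = False  # adds lambda2*L2 to the Student (experimental)
    self_entropy_mode: str = "shannon"  # bounded; "literal" is unbounded below
    similarity_squared: bool = True
    raw_denominator: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


def cosine_lr(step: int, total_steps: int, lr_init: float) -> float:
    """Cosine decay from ``lr_init`` at step 0 to ~0 at the final step."""
    if total_steps <= 1:
        return lr_init
    frac = step / (total_steps - 1)
    return lr_init * 0.5 * (1.0 + np.cos(np.pi * frac))


class _SGD:
    """Plain SGD with momentum over a name -> array parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], momentum: float,
                 grad_clip: float | None = None):
        self.params = params
        self.momentum = momentum
        self.grad_clip = grad_clip
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        if self.grad_clip is not None:
            norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if norm > self.grad_clip:
                scale = self.grad_clip / norm
                grads = {k: g * scale for k, g in grads.items()}
        for name, p in self.params.items():
            v = self.velocity[name]
            v *= self.momentum
            v -= lr * grads[name]
            p += v


def _check_reference(reference: ExpressionMatrix) -> list:
    if reference.cell_type is None:
        raise ValueError("reference must carry cell_type labels")
    if not reference.normalized:
        warnings.warn("reference does not look normalized; did you call normalize_log1p?")
    classes = sorted(set(map(str, reference.cell_type)))
    if len(classes) < 2:
        raise ValueError("reference has a single class; nothing to learn")
    counts = {c: int(np.sum(np.asarray(reference.cell_type).astype(str) == c))
              for c in classes}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        warnings.warn(f"classes with < 2 cells: {small}")
    return classes


def train_teacher(reference: ExpressionMatrix, config: TrainConfig,
                  mask: KnowledgeMask | None = None,
                  teacher_config: TeacherConfig | None = None
                  ) -> tuple[TeacherParams, list[dict]]:
    """Fit the Teacher on a labelled reference; returns (params, loss log).

    The per-minibatch loss is ``lambda1 * L1(softmax(logits), S(embeddings))
    + lambda2 * L2(logits, onehot)`` with the similarity kernel computed over
    the minibatch.
    """
    classes = _check_reference(reference)
    teacher_config = TeacherConfig() if teacher_config is None else teacher_config
    if mask is not None:
        teacher_config.m = mask.m
    params = init_teacher(reference.n_genes, len(classes), teacher_config,
                          mask=mask, seed=config.seed,
                          gene_names=list(reference.gene_names),
                          class_names=classes)
    X = reference.values
    Y = ob.onehot_encode([str(c) for c in reference.cell_type], classes)
    N = X.shape[0]
    rng = np.random.default_rng(config.seed + 1)
    opt = _SGD(params.param_dict(), config.momentum, config.grad_clip)
    steps_per_epoch = max(1, int(np.ceil(N / config.batch_size)))
    total_steps = config.epochs * steps_per_epoch
    log: list[dict] = []
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(N)
        ep_l1 = ep_l2 = 0.0
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            out, cache = teacher_forward(X[idx], params, return_cache=True)
            logits, emb = out["logits"], out["embedding"]
            P = ob._softmax(logits)
            S = ob.similarity_matrix(emb, squared=config.similarity_squared)
            l1, dP, dS = ob.clustering_divergence_loss(
                P, S, raw_denominator=config.raw_denominator, return_grads=True)
            d_logits = P * (dP - (dP * P).sum(axis=1, keepdims=True))
            d_emb = ob.similarity_backward(emb, S, dS)
            l2, d_ce = ob.cross_entropy_loss(logits, Y[idx], return_grads=True)
            grads = teacher_backward(
                params, cache,
                config.lambda1 * d_logits + config.lambda2 * d_ce,
                d_embedding=config.lambda1 * d_emb)
            opt.step(grads, cosine_lr(step, total_steps, config.lr))
            params.navigator.apply_mask()
            ep_l1 += l1
            ep_l2 += l2
            step += 1
        log.append({"epoch": epoch, "L1": ep_l1 / steps_per_epoch,
                    "L2": ep_l2 / steps_per_epoch,
                    "loss": (config.lambda1 * ep_l1 + config.lambda2 * ep_l2)
                            / steps_per_epoch})
    return params, log


def train_student(reference: ExpressionMatrix, teacher: TeacherParams,
                  config: TrainConfig) -> tuple[StudentParams, list[dict]]:
    """Distill the frozen Teacher into the Student MLP.

    Teacher logits over the reference are computed once and treated as
    constants. The Student loss is ``lambda3 * L3 + lambda4 * L4`` (plus
    ``lambda2 * L2`` only if ``use_hard_labels`` is set, an experimental
    deviation from the distillation-only protocol).
    """
    if teacher.gene_names is not None and list(reference.gene_names) != teacher.gene_names:
        raise ValueError("reference gene space does not match the teacher; "
                         "use data_io.align_genes first")
    X = reference.values
    N = X.shape[0]
    teacher_logits = predict_logits(teacher, X)
    student = init_student(reference.n_genes, teacher.k,
                           hidden=tuple(config.student_hidden),
                           seed=config.seed + 2,
                           gene_names=teacher.gene_names,
                           class_names=teacher.class_names)
    hard = None
    if config.use_hard_labels:
        if reference.cell_type is None:
            raise ValueError("use_hard_labels requires reference labels")
        hard = ob.onehot_encode([str(c) for c in reference.cell_type],
                                teacher.class_names)
    rng = np.random.default_rng(config.seed + 3)
    opt = _SGD(student.param_dict(), config.momentum, config.grad_clip)
    steps_per_epoch = max(1, int(np.ceil(N / config.batch_size)))
    total_steps = config.epochs * steps_per_epoch
    log: list[dict] = []
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(N)
        ep_l3 = ep_l4 = 0.0
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            logits, cache = student_forward(X[idx], student, return_cache=True)
            l3, d3 = ob.distillation_loss(logits, teacher_logits[idx],
                                          T=config.temperature, return_grads=True)
            if config.distill_rescale:
                d3 = d3 * config.temperature ** 2
            l4, d4 = ob.self_entropy_loss(logits, mode=config.self_entropy_mode,
                                          return_grads=True)
            d_logits = config.lambda3 * d3 + config.lambda4 * d4
            if hard is not None:
                _, d2 = ob.cross_entropy_loss(logits, hard[idx], return_grads=True)
                d_logits = d_logits + config.lambda2 * d2
            grads = student_backward(student, cache, d_logits)
            opt.step(grads, cosine_lr(step, total_steps, config.student_lr))
            ep_l3 += l3
            ep_l4 += l4
            step += 1
        log.append({"epoch": epoch, "L3": ep_l3 / steps_per_epoch,
                    "L4": ep_l4 / steps_per_epoch,
                    "loss": (config.lambda3 * ep_l3 + config.lambda4 * ep_l4)
                            / steps_per_epoch})
    return student, log


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _batched(X: np.ndarray, fn, batch: int = 1024) -> np.ndarray:
    return np.concatenate([fn(X[i:i + batch]) for i in range(0, X.shape[0], batch)])


def predict_logits(params: TeacherParams | StudentParams, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if isinstance(params, TeacherParams):
        return _batched(X, lambda xb: teacher_forward(xb, params)["logits"])
    return _batched(X, lambda xb: student_forward(xb, params))


def predict(params: TeacherParams | StudentParams,
            X: ExpressionMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell predicted label and class probabilities.

    Ties in the argmax resolve to the lowest class index. Returns
    ``(labels, probabilities)`` with labels as class-name strings when the
    model carries class names, else integer indices.
    """
    if isinstance(X, ExpressionMatrix):
        if params.gene_names is not None and list(X.gene_names) != params.gene_names:
            raise ValueError("gene space mismatch; use data_io.align_genes "
                             "to align the query to the model's gene list")
        values = X.values
    else:
        values = np.asarray(X, dtype=np.float64)
        if params.gene_names is not None and values.shape[1] != len(params.gene_names):
            raise ValueError("gene space mismatch; use data_io.align_genes")
    logits = predict_logits(params, values)
    probs = ob._softmax(logits)
    idx = np.argmax(logits, axis=1)  # argmax takes the first (lowest) index on ties
    if params.class_names is not None:
        labels = np.asarray(params.class_names, dtype=object)[idx]
    else:
        labels = idx
    return labels, probs


def embed(teacher: TeacherParams, X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Cells x h matrix of Teacher cell embeddings c_r."""
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=np.float64)
    return _batched(values, lambda xb: teacher_forward(xb, teacher)["embedding"])


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, teacher: TeacherParams | None = None,
                    student: StudentParams | None = None) -> None:
    """Serialize Teacher and/or Student (parameters, config, name lists)
    into a single ``.npz`` archive."""
    arrays: dict[str, np.ndarray] = {}
    meta: dict = {}
    if teacher is not None:
        for name, arr in teacher.param_dict().items():
            arrays[f"teacher/{name}"] = arr
        if teacher.navigator.mask is not None:
            arrays["teacher/mask"] = teacher.navigator.mask.mask
            meta["pathway_names"] = teacher.navigator.mask.pathway_names
        meta["teacher_config"] = asdict(teacher.config)
        meta["teacher_layers"] = len(teacher.cls_W)
        meta["gene_names"] = teacher.gene_names
        meta["class_names"] = teacher.class_names
        meta["mask_mode"] = teacher.navigator.mask_mode
    if student is not None:
        for name, arr in student.param_dict().items():
            arrays[f"student/{name}"] = arr
        meta["student_layers"] = student.n_layers
        meta.setdefault("gene_names", student.gene_names)
        meta.setdefault("class_names", student.class_names)
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path
                    ) -> tuple[TeacherParams | None, StudentParams | None]:
    with np.load(path, allow_pickle=False) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(arrays.pop("meta_json").tobytes().decode())
    teacher = student = None
    if "teacher_config" in meta:
        cfg = TeacherConfig(**meta["teacher_config"])
        mask = None
        if "teacher/mask" in arrays:
            mask = KnowledgeMask(mask=arrays["teacher/mask"],
                                 gene_names=meta["gene_names"],
                                 pathway_names=meta["pathway_names"])
        from .navigator import NavigatorParams

        nav = NavigatorParams(W=arrays["teacher/navigator.W"], mask=mask,
                              mask_mode=meta.get("mask_mode", "persistent"))
        n_layers = meta["teacher_layers"]
        teacher = TeacherParams(
            navigator=nav,
            cls_token=arrays["teacher/cls_token"],
            Wq=arrays["teacher/Wq"], Wk=arrays["teacher/Wk"], Wv=arrays["teacher/Wv"],
            Whq=arrays["teacher/Whq"], Whk=arrays["teacher/Whk"],
            Whv=arrays["teacher/Whv"], Wo=arrays["teacher/Wo"],
            cls_W=[arrays[f"teacher/cls_W{i}"] for i in range(n_layers)],
            cls_b=[arrays[f"teacher/cls_b{i}"] for i in range(n_layers)],
            ln_gamma=arrays.get("teacher/ln_gamma"),
            ln_beta=arrays.get("teacher/ln_beta"),
            config=cfg,
            gene_names=meta.get("gene_names"),
            class_names=meta.get("class_names"),
        )
    if "student_layers" in meta:
        n_layers = meta["student_layers"]
        student = StudentParams(
            weights=[arrays[f"student/W{i}"] for i in range(n_layers)],
            biases=[arrays[f"student/b{i}"] for i in range(n_layers)],
            gene_names=meta.get("gene_names"),
            class_names=meta.get("class_names"),
        )
    return teacher, student
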