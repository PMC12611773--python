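"""Distil a teacher's triplet similarity structure into a student encoder.

The student is any differentiable map from item features to a
representation vector; desk-scale implementations are a linear map and a
one-hidden-layer tanh network with hand-written backprop.  The objective
is the batch-mean KL between teacher pair distributions (computed at the
teacher temperature) and the student's softmax pair distribution at its
own, typically much larger, temperature, plus an l2 penalty pulling the
parameters back to their initialization snapshot.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._optim import Adam
from .sampling import PseudoLabelDataset
from .triplets import batch_choice_probabilities, batch_pair_similarities

__all__ = [
    "StudentEncoder",
    "LinearEncoder",
    "MLPEncoder",
    "DistillConfig",
    "alignment_kl_loss",
    "weight_decay_to_init",
    "distill",
]


class StudentEncoder(ABC):
    """Differentiable encoder with flat-parameter access and backprop.

    Subclasses store ``initial_parameters`` (the snapshot taken at
    construction) so the decay-to-initialization penalty is well defined.
    """

    initial_parameters: np.ndarray

    @abstractmethod
    def get_params(self) -> np.ndarray:
        """Current parameters as one flat vector (copy)."""

    @abstractmethod
    def set_params(self, flat: np.ndarray) -> None:
        """Load parameters from a flat vector."""

    @abstractmethod
    def encode(self, features: np.ndarray) -> np.ndarray:
        """Map (n, f) item features to (n, p) representations."""

    @abstractmethod
    def grad_params(self, features: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
        """Backprop: flat gradient of sum(grad_out * encode(features))."""


class LinearEncoder(StudentEncoder):
    """z = A f + c."""

    def __init__(self, A: np.ndarray, c: Optional[np.ndarray] = None):
        self.A = np.asarray(A, dtype=float).copy()
        self.c = np.zeros(self.A.shape[0]) if c is None else np.asarray(c, dtype=float).copy()
        self.initial_parameters = self.get_params()

    @staticmethod
    def random(out_dim: int, in_dim: int, scale: float = 0.1, seed: int = 0) -> "LinearEncoder":
        rng = np.random.default_rng(seed)
        return LinearEncoder(scale * rng.standard_normal((out_dim, in_dim)))

    def get_params(self) -> np.ndarray:
        return np.concatenate([self.A.ravel(), self.c]).copy()

    def set_params(self, flat: np.ndarray) -> None:
        nA = self.A.size
        self.A = flat[:nA].reshape(self.A.shape).copy()
        self.c = flat[nA:].copy()

    def encode(self, features: np.ndarray) -> np.ndarray:
        return features @ self.A.T + self.c

    def grad_params(self, features: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
        gA = grad_out.T @ features
        gc = grad_out.sum(axis=0)
        return np.concatenate([gA.ravel(), gc])


class MLPEncoder(StudentEncoder):
    """z = W2 tanh(W1 f + b1) + b2."""

    def __init__(self, W1: np.ndarray, b1: np.ndarray, W2: np.ndarray, b2: np.ndarray):
        self.W1 = np.asarray(W1, dtype=float).copy()
        self.b1 = np.asarray(b1, dtype=float).copy()
        self.W2 = np.asarray(W2, dtype=float).copy()
        self.b2 = np.asarray(b2, dtype=float).copy()
        self.initial_parameters = self.get_params()

    @staticmethod
    def random(out_dim: int, hidden: int, in_dim: int, scale: float = 0.1, seed: int = 0) -> "MLPEncoder":
        rng = np.random.default_rng(seed)
        return MLPEncoder(
            scale * rng.standard_normal((hidden, in_dim)),
            np.zeros(hidden),
            scale * rng.standard_normal((out_dim, hidden)),
            np.zeros(out_dim),
        )

    def get_params(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2.ravel(), self.b2]
        ).copy()

    def set_params(self, flat: np.ndarray) -> None:
        shapes = [self.W1.shape, self.b1.shape, self.W2.shape, self.b2.shape]
        arrays = []
        pos = 0
        for shp in shapes:
            size = int(np.prod(shp))
            arrays.append(flat[pos : pos + size].reshape(shp).copy())
            pos += size
        self.W1, self.b1, self.W2, self.b2 = arrays

    def encode(self, features: np.ndarray) -> np.ndarray:
        h = np.tanh(features @ self.W1.T + self.b1)
        return h @ self.W2.T + self.b2

    def grad_params(self, features: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
        h = np.tanh(features @ self.W1.T + self.b1)
        gW2 = grad_out.T @ h
        gb2 = grad_out.sum(axis=0)
        gh = grad_out @ self.W2
        gpre = gh * (1.0 - h * h)
        gW1 = gpre.T @ features
        gb1 = gpre.sum(axis=0)
        return np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])


@dataclass(frozen=True)
class DistillConfig:
    tau_teacher: float = 1.0
    tau_student: float = 100.0
    lambda_wd: float = 0.0
    batch_size: int = 256
    learning_rate: float = 0.01
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_teacher <= 0 or self.tau_student <= 0:
            raise ValueError("temperatures must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lambda_wd < 0:
            raise ValueError("lambda_wd must be nonnegative")


def alignment_kl_loss(
    teacher_soft: np.ndarray, student_sims: np.ndarray, cfg: DistillConfig
) -> float:
    """Batch-mean KL(teacher pair distribution || student softmax at tau_student)."""
    p = np.asarray(teacher_soft, dtype=float)
    s = np.asarray(student_sims, dtype=float)
    if p.shape != s.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("teacher_soft and student_sims must be matching (n, 3) arrays")
    q = batch_choice_probabilities(s, cfg.tau_student)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return float(np.mean(np.sum(plogp - p * np.log(q), axis=1)))


def weight_decay_to_init(
    params: np.ndarray, init_params: np.ndarray, lambda_wd: float
) -> float:
    """lambda * || params - init_params ||_2^2 over the flat parameter vector."""
    a = np.asarray(params, dtype=float)
    b = np.asarray(init_params, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parameter shapes must match")
    if lambda_wd < 0:
        raise ValueError("lambda_wd must be nonnegative")
    d = a - b
    return float(lambda_wd * np.dot(d, d))


def distill(
    student: StudentEncoder,
    data: PseudoLabelDataset,
    features: np.ndarray,
    cfg: Optional[DistillConfig] = None,
    loss_history: Optional[list] = None,
) -> StudentEncoder:
    """Fine-tune the student in place on frozen teacher soft labels.

    Mini-batch Adam on  alignment_kl_loss + weight_decay_to_init.  The
    pre-fit snapshot ``student.initial_parameters`` is left untouched for
    audit.  Returns the same (mutated) student.  Deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or DistillConfig()
    F = np.asarray(features, dtype=float)
    if data.triplets.size and data.triplets.max() >= F.shape[0]:
        raise ValueError("features must cover every item referenced by the dataset")
    theta0 = student.initial_parameters
    flat = student.get_params()
    opt = Adam([flat], lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    n = len(data)
    bs = min(cfg.batch_size, n)
    trips = data.triplets
    p_teacher = data.teacher_soft

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            batch = order[start : start + bs]
            t = trips[batch]
            p = p_teacher[batch]
            student.set_params(flat)
            Z = student.encode(F)
            sims = batch_pair_similarities(Z, t)
            q = batch_choice_probabilities(sims, cfg.tau_student)
            g = (q - p) / (len(batch) * cfg.tau_student)  # d mean-KL / d sims
            zi, zj, zk = Z[t[:, 0]], Z[t[:, 1]], Z[t[:, 2]]
            grad_z = np.zeros_like(Z)
            np.add.at(grad_z, t[:, 0], g[:, [0]] * zj + g[:, [1]] * zk)
            np.add.at(grad_z, t[:, 1], g[:, [0]] * zi + g[:, [2]] * zk)
            np.add.at(grad_z, t[:, 2], g[:, [1]] * zi + g[:, [2]] * zj)
            grad = student.grad_params(F, grad_z)
            grad += 2.0 * cfg.lambda_wd * (flat - theta0)
            opt.step([grad])
        if loss_history is not None:
            student.set_params(flat)
            sims = batch_pair_similarities(student.encode(F), trips)
            loss_history.append(
                alignment_kl_loss(p_teacher, sims, cfg)
                + weight_decay_to_init(flat, theta0, cfg.lambda_wd)
            )
    student.set_params(flat)
    return student
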