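"""Affine alignment of an embedding space to human triplet-choice structure.

Learns ``x' = W x + b`` so that the softmax choice rule applied to the
transformed pairwise dot products matches soft (probabilistic) human
pair-choice targets, while a scaled-identity penalty keeps the transform
close to the family ``c * I`` that preserves nearest-neighbour structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._optim import Adam
from .triplets import TripletResponseSet, batch_choice_probabilities, batch_pair_similarities

__all__ = [
    "AffineTransform",
    "TransformFitConfig",
    "apply_transform",
    "hard_align_loss",
    "soft_align_loss",
    "transform_regularizer",
    "fit_transform",
]


@dataclass
class AffineTransform:
    """Square linear map plus bias: x -> W x + b."""

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if self.b.shape != (self.W.shape[0],):
            raise ValueError("b must be a length-p vector")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))):
            raise ValueError("transform entries must be finite")

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @staticmethod
    def identity(p: int) -> "AffineTransform":
        return AffineTransform(np.eye(p), np.zeros(p))


@dataclass(frozen=True)
class TransformFitConfig:
    lambda_reg: float = 0.01
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def apply_transform(T: AffineTransform, X: np.ndarray) -> np.ndarray:
    """Map every row of X through W x + b."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != T.p:
        raise ValueError(f"X must have {T.p} columns, got shape {X.shape}")
    return X @ T.W.T + T.b


def hard_align_loss(transformed_sims: np.ndarray, responses: TripletResponseSet) -> float:
    """Mean negative log-likelihood of the chosen pairs (softmax at tau = 1)."""
    sims = np.asarray(transformed_sims, dtype=float)
    if responses.hard_choices is None:
        raise ValueError("responses must carry hard choices")
    if sims.shape != (len(responses), 3):
        raise ValueError("transformed_sims must be (n, 3) matching responses")
    if np.any(np.isnan(sims)):
        raise ValueError("similarities contain NaN")
    q = batch_choice_probabilities(sims, 1.0)
    chosen = q[np.arange(len(responses)), responses.hard_choices]
    return float(-np.mean(np.log(chosen)))


def soft_align_loss(
    transformed_sims: np.ndarray, soft_targets: np.ndarray, temperature: float = 1.0
) -> float:
    """Mean KL(p* || q) between soft targets and the softmax of the sims."""
    sims = np.asarray(transformed_sims, dtype=float)
    p = np.asarray(soft_targets, dtype=float)
    if sims.shape != p.shape or sims.ndim != 2 or sims.shape[1] != 3:
        raise ValueError("sims and targets must be matching (n, 3) arrays")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6) or np.any(p < -1e-12):
        raise ValueError("soft targets must be normalized")
    q = batch_choice_probabilities(sims, temperature)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)  # 0 log 0 := 0
    return float(np.mean(np.sum(plogp - p * np.log(q), axis=1)))


def transform_regularizer(W: np.ndarray, lambda_reg: float) -> float:
    """lambda * || W - (mean diag W) * I ||_F^2 — zero on scaled identities."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be nonnegative")
    p = W.shape[0]
    A = W - (np.trace(W) / p) * np.eye(p)
    return float(lambda_reg * np.sum(A * A))


def fit_transform(
    teacher_X: np.ndarray,
    responses: TripletResponseSet,
    cfg: Optional[TransformFitConfig] = None,
    loss_history: Optional[list] = None,
) -> AffineTransform:
    """Fit (W, b) by mini-batch Adam on soft-align loss + identity regularizer.

    W starts at the identity and b at zero, where the regularizer is zero
    and the transformed space equals the teacher space.  Deterministic
    given ``cfg.seed``.
    """
    cfg = cfg or TransformFitConfig()
    X = np.asarray(teacher_X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("teacher_X must be finite")
    if responses.soft_targets is None:
        raise ValueError("responses must carry soft targets (see uncertainty model)")
    p_dim = X.shape[1]
    trips = responses.triplets
    targets = responses.soft_targets
    n = len(trips)

    W = np.eye(p_dim)
    b = np.zeros(p_dim)
    opt = Adam([W, b], lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    bs = min(cfg.batch_size, n)
    eye = np.eye(p_dim)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            batch = order[start : start + bs]
            t = trips[batch]
            pt = targets[batch]
            Xp = X @ W.T + b
            sims = batch_pair_similarities(Xp, t)
            q = batch_choice_probabilities(sims, 1.0)
            g = (q - pt) / len(batch)  # d mean-KL / d sims
            xi, xj, xk = Xp[t[:, 0]], Xp[t[:, 1]], Xp[t[:, 2]]
            grad_xp = np.zeros_like(Xp)
            np.add.at(grad_xp, t[:, 0], g[:, [0]] * xj + g[:, [1]] * xk)
            np.add.at(grad_xp, t[:, 1], g[:, [0]] * xi + g[:, [2]] * xk)
            np.add.at(grad_xp, t[:, 2], g[:, [1]] * xi + g[:, [2]] * xj)
            grad_W = grad_xp.T @ X
            grad_b = grad_xp.sum(axis=0)
            # regularizer gradient: 2 lambda (W - (tr W / p) I) (traceless)
            A = W - (np.trace(W) / p_dim) * eye
            grad_W += 2.0 * cfg.lambda_reg * A
            opt.step([grad_W, grad_b])
        if loss_history is not None:
            Xp = X @ W.T + b
            sims = batch_pair_similarities(Xp, trips)
            loss_history.append(
                soft_align_loss(sims, targets) + transform_regularizer(W, cfg.lambda_reg)
            )
    return AffineTransform(W, b)
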