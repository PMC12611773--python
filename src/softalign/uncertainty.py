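"""Variational per-item concept embeddings capturing response uncertainty.

Each item gets a mean-field Gaussian posterior (mu, sigma) over a latent
concept space.  Triplet choice probabilities are Monte-Carlo averages of
the softmax choice rule applied to sampled embeddings; disagreement among
annotators shows up as predictive entropy.  Fitting maximizes the expected
choice log-likelihood (reparameterization trick) with a standard-normal
prior regularizer; gradients are analytic (no autodiff dependency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._optim import Adam
from .triplets import (
    ChoiceDistribution,
    Triplet,
    TripletResponseSet,
    batch_choice_probabilities,
    batch_pair_similarities,
)

__all__ = [
    "VariationalEmbedding",
    "MCSettings",
    "UncertaintyFitConfig",
    "sample_embedding",
    "mc_triplet_probabilities",
    "batch_mc_probabilities",
    "fit_uncertainty_model",
]


@dataclass
class VariationalEmbedding:
    """Mean/variance concept embedding: one Gaussian per item and dimension."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 2:
            raise ValueError("mu and sigma must be matching (items, d) matrices")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")

    @property
    def n_items(self) -> int:
        return self.mu.shape[0]

    @property
    def d(self) -> int:
        return self.mu.shape[1]


@dataclass(frozen=True)
class MCSettings:
    """Monte-Carlo estimate settings: number of samples and the stream seed."""

    n_samples: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class UncertaintyFitConfig:
    learning_rate: float = 0.05
    epochs: int = 150
    batch_size: int = 256
    prior_weight: float = 1.0
    val_fraction: float = 0.2
    patience: int = 15
    init_sigma: float = 0.1


def sample_embedding(ve: VariationalEmbedding, seed: int) -> np.ndarray:
    """One reparameterized draw Y = mu + sigma * eps, eps ~ N(0, 1)."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(ve.mu.shape)
    return ve.mu + ve.sigma * eps


def batch_mc_probabilities(
    ve: VariationalEmbedding, triplets: np.ndarray, mc: MCSettings = MCSettings()
) -> np.ndarray:
    """(n, 3) Monte-Carlo choice probabilities, averaged over sampled embeddings.

    Each sample r applies the softmax choice rule (tau = 1) to the pairwise
    dot products of a fresh draw of the full embedding matrix.
    """
    triplets = np.asarray(triplets, dtype=np.int64)
    rng = np.random.default_rng(mc.seed)
    acc = np.zeros((len(triplets), 3))
    for _ in range(mc.n_samples):
        y = ve.mu + ve.sigma * rng.standard_normal(ve.mu.shape)
        sims = batch_pair_similarities(y, triplets)
        acc += batch_choice_probabilities(sims, 1.0)
    p = acc / mc.n_samples
    return p / p.sum(axis=1, keepdims=True)


def mc_triplet_probabilities(
    ve: VariationalEmbedding, t: Triplet, mc: MCSettings = MCSettings()
) -> ChoiceDistribution:
    """Monte-Carlo posterior choice distribution for one triplet."""
    p = batch_mc_probabilities(ve, np.array([t.as_tuple()]), mc)[0]
    return ChoiceDistribution.from_array(p)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: float) -> float:
    return float(np.log(np.expm1(y)))


def fit_uncertainty_model(
    responses: TripletResponseSet,
    d: int,
    config: Optional[UncertaintyFitConfig] = None,
    seed: int = 0,
    n_items: Optional[int] = None,
) -> VariationalEmbedding:
    """Fit the variational embedding to hard odd-one-out choices.

    Minimizes  mean NLL of the chosen pair under a reparameterized sample
    plus (prior_weight / n) * KL(q || N(0, I)),  by Adam on (mu, rho) with
    sigma = softplus(rho).  A seeded 20% split provides early stopping on
    held-out NLL.  Deterministic given ``seed``.
    """
    if responses.hard_choices is None or len(responses) == 0:
        raise ValueError("responses must contain hard choices and be non-empty")
    if d < 1:
        raise ValueError("d must be >= 1")
    cfg = config or UncertaintyFitConfig()
    m = n_items if n_items is not None else responses.n_items

    rng = np.random.default_rng(seed)
    n = len(responses)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n >= 5 else 0
    val_idx = perm[:n_val]
    train_idx = perm[n_val:]
    trips = responses.triplets
    choices = responses.hard_choices

    mu = 0.1 * rng.standard_normal((m, d))
    rho = np.full((m, d), _softplus_inv(cfg.init_sigma))
    opt = Adam([mu, rho], lr=cfg.learning_rate)

    def heldout_nll(mu_a: np.ndarray, sig_a: np.ndarray) -> float:
        if n_val == 0:
            return np.nan
        ve = VariationalEmbedding(mu_a, sig_a)
        p = batch_mc_probabilities(ve, trips[val_idx], MCSettings(n_samples=10, seed=seed + 1))
        return float(-np.mean(np.log(p[np.arange(n_val), choices[val_idx]] + 1e-12)))

    best = (np.inf, mu.copy(), rho.copy())
    stale = 0
    n_train = len(train_idx)
    bs = min(cfg.batch_size, n_train)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, bs):
            batch = train_idx[order[start : start + bs]]
            t = trips[batch]
            c = choices[batch]
            sigma = _softplus(rho)
            eps = rng.standard_normal((m, d))
            y = mu + sigma * eps
            sims = batch_pair_similarities(y, t)
            q = batch_choice_probabilities(sims, 1.0)
            # dNLL/ds for the softmax choice likelihood
            g = q.copy()
            g[np.arange(len(batch)), c] -= 1.0
            g /= len(batch)
            yi, yj, yk = y[t[:, 0]], y[t[:, 1]], y[t[:, 2]]
            grad_y = np.zeros_like(y)
            np.add.at(grad_y, t[:, 0], g[:, [0]] * yj + g[:, [1]] * yk)
            np.add.at(grad_y, t[:, 1], g[:, [0]] * yi + g[:, [2]] * yk)
            np.add.at(grad_y, t[:, 2], g[:, [1]] * yi + g[:, [2]] * yj)
            w = cfg.prior_weight / n
            grad_mu = grad_y + w * mu
            grad_sigma = grad_y * eps + w * (sigma - 1.0 / sigma)
            grad_rho = grad_sigma / (1.0 + np.exp(-rho))  # d softplus / d rho
            opt.step([grad_mu, grad_rho])
        if n_val:
            nll = heldout_nll(mu, _softplus(rho))
            if nll < best[0] - 1e-5:
                best = (nll, mu.copy(), rho.copy())
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if n_val and np.isfinite(best[0]):
        mu, rho = best[1], best[2]
    return VariationalEmbedding(mu, _softplus(rho))
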