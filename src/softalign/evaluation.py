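"""Alignment evaluation: accuracy vs humans, RSA, noise ceilings, RT analyses.

Also houses the hierarchical distance-change contrast (z-scored pairwise
distances before/after a checkpoint, summarized per pair-relation level)
and item-level bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from .synthetic import GroundTruthSpace

__all__ = [
    "RSM",
    "HierarchyContrast",
    "RELATION_LEVELS",
    "rsm",
    "rsa_spearman",
    "majority_response",
    "noise_ceiling_loo",
    "preprocess_rts",
    "exclude_participants",
    "entropy_rt_correlation",
    "distance_change_by_level",
    "bootstrap_ci",
    "relative_improvement",
]

logger = logging.getLogger(__name__)

RELATION_LEVELS = (
    "same_subordinate",
    "same_basic",
    "same_superordinate",
    "different_superordinate",
)


@dataclass
class RSM:
    """Representational similarity matrix under a pearson or cosine kernel."""

    matrix: np.ndarray
    kernel: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("RSM must be square")
        if self.kernel not in ("pearson", "cosine"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]


@dataclass(frozen=True)
class HierarchyContrast:
    relation_level: str
    mean_z_change: float
    n_pairs: int


def rsm(X: np.ndarray, kernel: str = "pearson") -> RSM:
    """Pairwise-kernel similarity matrix over embedding rows.

    ``pearson`` is the cosine of row-centred vectors; ``cosine`` uses the
    raw rows.  Both put exactly 1 on the diagonal.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a matrix with at least 2 rows")
    if kernel == "pearson":
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Xc, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(f"row {int(bad[0])} is constant; pearson kernel undefined")
        U = Xc / norms[:, None]
    elif kernel == "cosine":
        norms = np.linalg.norm(X, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(f"row {int(bad[0])} is all-zero; cosine kernel undefined")
        U = X / norms[:, None]
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    M = U @ U.T
    np.fill_diagonal(M, 1.0)
    return RSM(matrix=M, kernel=kernel)


def rsa_spearman(rsm_a: RSM, rsm_b: RSM) -> float:
    """Spearman rank correlation of the strictly-upper-triangle entries."""
    if rsm_a.n != rsm_b.n:
        raise ValueError("RSMs must have the same dimension")
    if rsm_a.n < 3:
        raise ValueError("need at least 3 items")
    rho, _ = spearmanr(rsm_a.upper_triangle(), rsm_b.upper_triangle())
    return float(rho)


def majority_response(counts: Sequence[int], seed: int = 0) -> int:
    """Modal pair code; ties broken uniformly at random (seeded)."""
    c = np.asarray(counts, dtype=np.int64)
    if c.shape != (3,) or np.any(c < 0):
        raise ValueError("counts must be three nonnegative integers")
    if c.sum() == 0:
        raise ValueError("counts must not be all zero")
    winners = np.flatnonzero(c == c.max())
    if len(winners) == 1:
        return int(winners[0])
    rng = np.random.default_rng(seed)
    pick = int(rng.choice(winners))
    logger.debug("majority tie among pairs %s; picked %d", winners.tolist(), pick)
    return pick


def noise_ceiling_loo(
    triplet_choices: Sequence[Sequence[int]], seed: int = 0
) -> float:
    """Leave-one-out human-to-human agreement.

    ``triplet_choices`` holds, per triplet, the list of pair codes chosen
    by the annotators who saw it.  For every held-out response, compare it
    to the majority of the remaining responses for that triplet; average
    over all held-out comparisons.  Triplets with a single response are
    excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    matches: list[float] = []
    n_skipped = 0
    for choices in triplet_choices:
        choices = np.asarray(choices, dtype=np.int64)
        if len(choices) < 2:
            n_skipped += 1
            continue
        for h in range(len(choices)):
            rest = np.delete(choices, h)
            counts = np.bincount(rest, minlength=3)[:3]
            maj = majority_response(counts, seed=int(rng.integers(2**31)))
            matches.append(float(choices[h] == maj))
    if n_skipped:
        logger.warning("noise_ceiling_loo: excluded %d single-response triplets", n_skipped)
    if not matches:
        raise ValueError("no triplet has >= 2 responses")
    return float(np.mean(matches))


def preprocess_rts(rts: Sequence[float], max_rt: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Log-transform RTs and mask out implausibly slow trials.

    Returns (log RTs, inclusion mask).  Trials strictly longer than
    ``max_rt`` seconds are excluded; there is no lower bound.
    """
    rts = np.asarray(rts, dtype=float)
    if np.any(rts <= 0):
        raise ValueError("response times must be positive")
    return np.log(rts), rts <= max_rt


def exclude_participants(
    catch_accuracy: Sequence[float],
    n_missing: Sequence[int],
    min_catch_accuracy: float = 0.90,
    max_missing: int = 10,
) -> np.ndarray:
    """Boolean keep-mask: catch accuracy >= 90% and at most 10 missed trials."""
    acc = np.asarray(catch_accuracy, dtype=float)
    miss = np.asarray(n_missing, dtype=np.int64)
    if acc.shape != miss.shape:
        raise ValueError("records must align")
    if np.any((acc < 0) | (acc > 1)):
        raise ValueError("catch accuracy must lie in [0, 1]")
    return (acc >= min_catch_accuracy) & (miss <= max_missing)


def entropy_rt_correlation(
    model_entropies: Sequence[float], mean_log_rts: Sequence[float]
) -> float:
    """Spearman correlation between per-triplet entropies and mean log RTs."""
    e = np.asarray(model_entropies, dtype=float)
    r = np.asarray(mean_log_rts, dtype=float)
    if e.shape != r.shape or e.ndim != 1 or len(e) < 3:
        raise ValueError("inputs must be equal-length 1-d arrays with >= 3 entries")
    rho, _ = spearmanr(e, r)
    return float(rho)


def _pair_relation_levels(space: GroundTruthSpace) -> np.ndarray:
    """Relation-level index (into RELATION_LEVELS) for each pdist pair."""
    sub = space.subordinate_label
    bas = space.basic_label
    sup = space.superordinate_label
    n = len(sub)
    ii, jj = np.triu_indices(n, k=1)
    levels = np.full(len(ii), 3, dtype=np.int64)
    levels[sup[ii] == sup[jj]] = 2
    levels[bas[ii] == bas[jj]] = 1
    levels[sub[ii] == sub[jj]] = 0
    return levels


def distance_change_by_level(
    X_before: np.ndarray,
    X_after: np.ndarray,
    space: GroundTruthSpace,
    cluster_aggregate: bool = True,
) -> list[HierarchyContrast]:
    """Mean z-scored pairwise-distance change per hierarchy relation level.

    All pairwise Euclidean distances are z-scored within each checkpoint
    (so global rescaling cancels); the per-pair change is z_after -
    z_before.  With ``cluster_aggregate`` the pairs of a relation level are
    first averaged within basic-category groups (keyed by the basic label
    of the pair's first item) before averaging across groups, a fixed-
    effect stand-in for a category-level random effect.
    """
    Xb = np.asarray(X_before, dtype=float)
    Xa = np.asarray(X_after, dtype=float)
    if Xb.shape[0] != Xa.shape[0] or Xb.shape[0] != space.n_items:
        raise ValueError("checkpoints must cover the same items as the label space")

    def zscored(X: np.ndarray) -> np.ndarray:
        d = pdist(X)
        sd = d.std()
        if sd == 0:
            return np.zeros_like(d)
        return (d - d.mean()) / sd

    change = zscored(Xa) - zscored(Xb)
    levels = _pair_relation_levels(space)
    n = space.n_items
    ii, _ = np.triu_indices(n, k=1)
    group_key = space.basic_label[ii]

    out = []
    for lvl_idx, lvl_name in enumerate(RELATION_LEVELS):
        mask = levels == lvl_idx
        if not np.any(mask):
            continue
        if cluster_aggregate:
            keys = group_key[mask]
            vals = change[mask]
            means = [vals[keys == k].mean() for k in np.unique(keys)]
            mz = float(np.mean(means))
        else:
            mz = float(change[mask].mean())
        out.append(HierarchyContrast(lvl_name, mz, int(mask.sum())))
    return out


def bootstrap_ci(
    per_item_scores: Sequence[float],
    n_boot: int = 100,
    sample_size: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Item-level percentile bootstrap of the mean: (mean, lo95, hi95)."""
    scores = np.asarray(per_item_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    if n_boot < 2 or sample_size < 1:
        raise ValueError("need n_boot >= 2 and sample_size >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(scores), size=(n_boot, sample_size))
    means = scores[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(scores.mean()), float(lo), float(hi)


def relative_improvement(before: float, after: float) -> float:
    """Relative performance increase in percent: 100 * (after - before) / before."""
    if before == 0:
        raise ValueError("baseline must be nonzero")
    return 100.0 * (after - before) / before
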