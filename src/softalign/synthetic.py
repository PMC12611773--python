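"""Synthetic ground truth: hierarchical concept spaces, annotators, response times.

Items are abstract vectors drawn from a three-level nested Gaussian
hierarchy (superordinate -> basic -> subordinate items).  Simulated
annotators answer odd-one-out triplets through the softmax choice rule
with a temperature and a lapse rate, and emit response times whose log
is linear in the entropy of their choice distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .triplets import TripletResponseSet, batch_pair_similarities, batch_choice_probabilities, entropy

__all__ = [
    "GroundTruthSpace",
    "AnnotatorModel",
    "generate_hierarchy",
    "simulate_responses",
    "simulate_response_time",
]


@dataclass
class GroundTruthSpace:
    """Item embeddings with nested subordinate/basic/superordinate labels."""

    embeddings: np.ndarray
    superordinate_label: np.ndarray
    basic_label: np.ndarray
    subordinate_label: np.ndarray
    generation_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.embeddings.shape[0]
        for name in ("superordinate_label", "basic_label", "subordinate_label"):
            lab = np.asarray(getattr(self, name), dtype=np.int64)
            if lab.shape != (n,):
                raise ValueError(f"{name} must have one entry per item")
            setattr(self, name, lab)
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("embeddings must be finite")
        # nesting: same subordinate => same basic => same superordinate
        for sub in np.unique(self.subordinate_label):
            rows = self.subordinate_label == sub
            if len(np.unique(self.basic_label[rows])) != 1:
                raise ValueError("subordinate labels must nest within basic labels")
        for bas in np.unique(self.basic_label):
            rows = self.basic_label == bas
            if len(np.unique(self.superordinate_label[rows])) != 1:
                raise ValueError("basic labels must nest within superordinate labels")

    @property
    def n_items(self) -> int:
        return self.embeddings.shape[0]

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]


@dataclass(frozen=True)
class AnnotatorModel:
    """Softmax annotator with lapses and a log-linear response-time model."""

    temperature: float = 1.0
    lapse_rate: float = 0.0
    rt_intercept: float = 0.0
    rt_slope: float = 1.0
    rt_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be nonnegative")


def generate_hierarchy(
    n_super: int,
    n_basic_per_super: int,
    n_items_per_basic: int,
    dim: int,
    level_spreads: Sequence[float] = (10.0, 2.0, 0.5),
    seed: int = 0,
) -> GroundTruthSpace:
    """Draw a nested isotropic-Gaussian hierarchy of item embeddings.

    Superordinate centroids are N(0, spread_0^2 I); each basic centroid is
    drawn around its superordinate centroid with spread_1; items are drawn
    around subordinate centroids with spread_2.  Each basic category is
    split into two subordinate groups (one when it has a single item) so
    that all four pair-relation levels are populated.
    """
    counts = dict(
        n_super=n_super,
        n_basic_per_super=n_basic_per_super,
        n_items_per_basic=n_items_per_basic,
        dim=dim,
    )
    for name, v in counts.items():
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    spreads = tuple(float(s) for s in level_spreads)
    if len(spreads) != 3 or any(s <= 0 for s in spreads):
        raise ValueError("level_spreads must be three positive reals")

    rng = np.random.default_rng(seed)
    sup_spread, basic_spread, item_spread = spreads

    embeddings = []
    sup_labels, basic_labels, sub_labels = [], [], []
    basic_id = 0
    for s in range(n_super):
        sup_centroid = rng.normal(0.0, sup_spread, size=dim)
        for _ in range(n_basic_per_super):
            basic_centroid = sup_centroid + rng.normal(0.0, basic_spread, size=dim)
            n_sub = 2 if n_items_per_basic >= 2 else 1
            sizes = [n_items_per_basic - n_items_per_basic // 2, n_items_per_basic // 2]
            for which in range(n_sub):
                sub_centroid = basic_centroid + rng.normal(0.0, item_spread, size=dim)
                for _ in range(sizes[which]):
                    embeddings.append(sub_centroid + rng.normal(0.0, item_spread, size=dim))
                    sup_labels.append(s)
                    basic_labels.append(basic_id)
                    sub_labels.append(2 * basic_id + which)
            basic_id += 1

    return GroundTruthSpace(
        embeddings=np.asarray(embeddings, dtype=float),
        superordinate_label=np.asarray(sup_labels),
        basic_label=np.asarray(basic_labels),
        subordinate_label=np.asarray(sub_labels),
        generation_params={**counts, "level_spreads": spreads, "seed": seed},
    )


def simulate_response_time(choice_entropy: float, annot: AnnotatorModel, seed: int) -> float:
    """One response time: log RT = intercept + slope * entropy + noise."""
    if choice_entropy < 0:
        raise ValueError("entropy must be nonnegative")
    rng = np.random.default_rng(seed)
    log_rt = (
        annot.rt_intercept
        + annot.rt_slope * choice_entropy
        + rng.normal(0.0, annot.rt_noise_sd)
    )
    return float(np.exp(log_rt))


def simulate_responses(
    space: GroundTruthSpace,
    triplets: np.ndarray,
    annot: AnnotatorModel,
    n_annotators_per_triplet: int = 1,
    seed: int = 0,
) -> TripletResponseSet:
    """Sample annotator odd-one-out choices and response times for ``triplets``.

    Each annotator lapses (chooses a pair uniformly) with probability
    ``annot.lapse_rate``, otherwise samples a pair from the softmax of the
    ground-truth dot-product similarities at ``annot.temperature``.  The
    per-response RT is driven by the entropy of the annotator's effective
    choice distribution (lapse-mixed).
    """
    triplets = np.asarray(triplets, dtype=np.int64)
    if triplets.ndim != 2 or triplets.shape[1] != 3:
        raise ValueError("triplets must be (n, 3)")
    if triplets.size and (triplets.min() < 0 or triplets.max() >= space.n_items):
        raise IndexError("triplet index out of range for space")
    if n_annotators_per_triplet < 1:
        raise ValueError("n_annotators_per_triplet must be >= 1")

    sims = batch_pair_similarities(space.embeddings, triplets)
    p_soft = batch_choice_probabilities(sims, annot.temperature)
    # effective choice distribution after the lapse mixture
    p_eff = (1.0 - annot.lapse_rate) * p_soft + annot.lapse_rate / 3.0

    n_t = len(triplets)
    n_a = n_annotators_per_triplet
    # per-annotator substreams split from one root seed
    child_seeds = np.random.SeedSequence(seed).spawn(n_a)

    all_trip, all_choice, all_pid, all_rt = [], [], [], []
    for a in range(n_a):
        rng = np.random.default_rng(child_seeds[a])
        u = rng.random(n_t)
        cdf = np.cumsum(p_eff, axis=1)
        choices = (u[:, None] > cdf).sum(axis=1)
        ent = np.array([entropy(p_eff[t]) for t in range(n_t)])
        log_rt = (
            annot.rt_intercept
            + annot.rt_slope * ent
            + rng.normal(0.0, annot.rt_noise_sd, size=n_t)
        )
        all_trip.append(triplets)
        all_choice.append(choices)
        all_pid.append(np.full(n_t, a))
        all_rt.append(np.exp(log_rt))

    return TripletResponseSet(
        triplets=np.concatenate(all_trip),
        hard_choices=np.concatenate(all_choice),
        participant_ids=np.concatenate(all_pid),
        rt_seconds=np.concatenate(all_rt),
    )
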