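"""Triplet odd-one-out primitives.

Similarity is the raw dot product between item embeddings.  A triplet
``(i, j, k)`` has three candidate pairs, always enumerated in the fixed
order ``(i,j) < (i,k) < (j,k)``; pair codes 0, 1, 2 (string codes
``"ij"``, ``"ik"``, ``"jk"``) refer to that order everywhere in this
package.  The pair with the highest similarity is the "closest pair";
the remaining item is the odd one out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PAIR_CODES",
    "Triplet",
    "TripletSimilarities",
    "ChoiceDistribution",
    "TripletResponseSet",
    "pair_similarities",
    "batch_pair_similarities",
    "choose_odd_one_out",
    "choice_probabilities",
    "batch_choice_probabilities",
    "odd_one_out_accuracy",
    "triplet_entropy",
    "entropy",
    "response_distribution_entropy",
]

#: Fixed pair order; index into this tuple is the canonical pair code.
PAIR_CODES: tuple[str, str, str] = ("ij", "ik", "jk")

# Given the chosen pair code, the position (0=i, 1=j, 2=k) of the odd item.
_ODD_POSITION = {0: 2, 1: 1, 2: 0}


@dataclass(frozen=True)
class Triplet:
    """Three pairwise-distinct item indices."""

    i: int
    j: int
    k: int

    def __post_init__(self) -> None:
        if len({self.i, self.j, self.k}) != 3:
            raise ValueError(f"triplet indices must be distinct, got {(self.i, self.j, self.k)}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.i, self.j, self.k)


@dataclass(frozen=True)
class TripletSimilarities:
    """Dot-product similarities for the three pairs of a triplet."""

    s_ij: float
    s_ik: float
    s_jk: float

    def as_array(self) -> np.ndarray:
        return np.array([self.s_ij, self.s_ik, self.s_jk], dtype=float)


@dataclass(frozen=True)
class ChoiceDistribution:
    """Probability over the three pairs, in fixed pair order."""

    p_ij: float
    p_ik: float
    p_jk: float
    temperature: float = 1.0

    def __post_init__(self) -> None:
        p = self.as_array()
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"not a normalized distribution: {tuple(p)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_ij, self.p_ik, self.p_jk], dtype=float)

    @staticmethod
    def from_array(p: np.ndarray, temperature: float = 1.0) -> "ChoiceDistribution":
        return ChoiceDistribution(float(p[0]), float(p[1]), float(p[2]), temperature)


@dataclass
class TripletResponseSet:
    """A collection of triplets with hard and/or soft responses.

    ``triplets`` has shape (n, 3).  ``hard_choices`` holds one pair code
    (0/1/2) per response row; responses may repeat triplets (several
    annotators).  ``soft_targets`` is an optional (n, 3) simplex array
    aligned with ``triplets``.
    """

    triplets: np.ndarray
    hard_choices: Optional[np.ndarray] = None
    soft_targets: Optional[np.ndarray] = None
    participant_ids: Optional[np.ndarray] = None
    rt_seconds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.triplets = np.asarray(self.triplets, dtype=np.int64)
        if self.triplets.ndim != 2 or self.triplets.shape[1] != 3:
            raise ValueError("triplets must be an (n, 3) array")
        same = (
            (self.triplets[:, 0] == self.triplets[:, 1])
            | (self.triplets[:, 0] == self.triplets[:, 2])
            | (self.triplets[:, 1] == self.triplets[:, 2])
        )
        if np.any(same):
            raise ValueError(f"triplet row {int(np.flatnonzero(same)[0])} has repeated indices")
        if self.hard_choices is not None:
            self.hard_choices = np.asarray(self.hard_choices, dtype=np.int64)
            if self.hard_choices.shape != (len(self.triplets),):
                raise ValueError("hard_choices length must match triplets")
            if np.any((self.hard_choices < 0) | (self.hard_choices > 2)):
                raise ValueError("hard_choices must be pair codes in {0, 1, 2}")
        if self.soft_targets is not None:
            self.soft_targets = np.asarray(self.soft_targets, dtype=float)
            if self.soft_targets.shape != (len(self.triplets), 3):
                raise ValueError("soft_targets must be (n, 3)")
            if np.any(self.soft_targets < -1e-12) or np.any(
                np.abs(self.soft_targets.sum(axis=1) - 1.0) > 1e-6
            ):
                raise ValueError("soft_targets rows must be normalized")

    def __len__(self) -> int:
        return len(self.triplets)

    @property
    def n_items(self) -> int:
        return int(self.triplets.max()) + 1


def pair_similarities(emb: np.ndarray, t: Triplet) -> TripletSimilarities:
    """Dot products between the three item pairs of ``t`` under ``emb``."""
    emb = np.asarray(emb, dtype=float)
    n = emb.shape[0]
    for idx in t.as_tuple():
        if not (0 <= idx < n):
            raise IndexError(f"item index {idx} out of range for {n} items")
    xi, xj, xk = emb[t.i], emb[t.j], emb[t.k]
    if not np.all(np.isfinite([xi, xj, xk])):
        raise ValueError("embedding rows must be finite")
    return TripletSimilarities(float(xi @ xj), float(xi @ xk), float(xj @ xk))


def batch_pair_similarities(emb: np.ndarray, triplets: np.ndarray) -> np.ndarray:
    """(n, 3) array of pair dot products, columns in fixed pair order."""
    emb = np.asarray(emb, dtype=float)
    triplets = np.asarray(triplets, dtype=np.int64)
    if triplets.size and (triplets.min() < 0 or triplets.max() >= emb.shape[0]):
        raise IndexError("triplet index out of range")
    xi = emb[triplets[:, 0]]
    xj = emb[triplets[:, 1]]
    xk = emb[triplets[:, 2]]
    return np.stack(
        [np.sum(xi * xj, axis=1), np.sum(xi * xk, axis=1), np.sum(xj * xk, axis=1)],
        axis=1,
    )


def choose_odd_one_out(s: TripletSimilarities) -> tuple[int, int]:
    """Return (closest pair code, odd item position 0/1/2).

    Ties are broken by the fixed pair order ij < ik < jk.
    """
    arr = s.as_array()
    if np.any(np.isnan(arr)):
        raise ValueError("similarities contain NaN")
    pair = int(np.argmax(arr))  # argmax takes the first maximum: the tie rule
    return pair, _ODD_POSITION[pair]


def _softmax_rows(s: np.ndarray, temperature: float) -> np.ndarray:
    z = s / temperature
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def choice_probabilities(s: TripletSimilarities, temperature: float = 1.0) -> ChoiceDistribution:
    """Softmax choice rule over the three pair similarities."""
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    p = _softmax_rows(s.as_array(), temperature)
    return ChoiceDistribution.from_array(p, temperature)


def batch_choice_probabilities(sims: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    """Row-wise softmax of an (n, 3) similarity array."""
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return _softmax_rows(np.asarray(sims, dtype=float), temperature)


def odd_one_out_accuracy(
    model_choices: Sequence[int] | np.ndarray, reference_choices: Sequence[int] | np.ndarray
) -> float:
    """Fraction of responses where the model's closest pair matches the reference."""
    a = np.asarray(model_choices)
    b = np.asarray(reference_choices)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("choice lists must be equal-length, non-empty 1-d sequences")
    return float(np.mean(a == b))


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats, with 0 * log 0 := 0."""
    p = np.asarray(p, dtype=float)
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def triplet_entropy(p: ChoiceDistribution) -> float:
    """Entropy (nats) of a pair-choice distribution."""
    return entropy(p.as_array())


def response_distribution_entropy(counts: Sequence[int]) -> float:
    """Entropy of empirical pair-choice frequencies from response counts."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (3,) or np.any(c < 0):
        raise ValueError("counts must be three nonnegative integers")
    total = c.sum()
    if total < 1:
        raise ValueError("counts must sum to at least 1")
    return entropy(c / total)
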