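"""Triplet sampling strategies, k-means clustering, and teacher pseudo-labels.

Strategies: uniform random triplets; boundary triplets (two items sharing a
class or cluster label plus one outsider); and stratified triplets drawn by
superclass first so over-represented fine-grained classes do not dominate.
Pseudo-labelling scores every triplet with the softmax choice distribution
of a (transformed) teacher space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .triplets import batch_choice_probabilities, batch_pair_similarities

__all__ = [
    "ClusterAssignment",
    "PseudoLabelDataset",
    "sample_random_triplets",
    "sample_class_boundary_triplets",
    "cluster_representations",
    "select_k_elbow",
    "sample_cluster_boundary_triplets",
    "sample_levels_triplets",
    "pseudolabel",
]


@dataclass
class ClusterAssignment:
    """k-means output: dense cluster ids per item plus the final inertia."""

    labels: np.ndarray
    n_clusters: int
    inertia: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() >= self.n_clusters:
            raise ValueError("cluster ids must lie in [0, n_clusters)")


@dataclass
class PseudoLabelDataset:
    """Triplets with teacher soft pair distributions and hard argmax choices."""

    triplets: np.ndarray
    teacher_soft: np.ndarray
    teacher_choice: np.ndarray

    def __post_init__(self) -> None:
        self.triplets = np.asarray(self.triplets, dtype=np.int64)
        self.teacher_soft = np.asarray(self.teacher_soft, dtype=float)
        self.teacher_choice = np.asarray(self.teacher_choice, dtype=np.int64)
        n = len(self.triplets)
        if self.teacher_soft.shape != (n, 3) or self.teacher_choice.shape != (n,):
            raise ValueError("inconsistent dataset shapes")
        if not np.array_equal(self.teacher_choice, np.argmax(self.teacher_soft, axis=1)):
            raise ValueError("teacher_choice must be the argmax of teacher_soft")

    def __len__(self) -> int:
        return len(self.triplets)


def sample_random_triplets(n_items: int, n: int, seed: int = 0) -> np.ndarray:
    """n triplets of three distinct items chosen uniformly without replacement."""
    if n_items < 3:
        raise ValueError("need at least 3 items")
    rng = np.random.default_rng(seed)
    # vectorized distinct sampling: first uniform, then shifted draws
    i = rng.integers(0, n_items, size=n)
    j = rng.integers(0, n_items - 1, size=n)
    j = np.where(j >= i, j + 1, j)
    k = rng.integers(0, n_items - 2, size=n)
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    k = np.where(k >= lo, k + 1, k)
    k = np.where(k >= hi, k + 1, k)
    return np.stack([i, j, k], axis=1)


def _boundary_from_labels(labels: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.asarray(labels)
    classes, inverse = np.unique(labels, return_inverse=True)
    members = [np.flatnonzero(inverse == c) for c in range(len(classes))]
    eligible = [c for c, m in enumerate(members) if len(m) >= 2]
    if len(classes) < 2 or not eligible:
        raise ValueError("need >= 2 classes and one class with >= 2 members")
    out = np.empty((n, 3), dtype=np.int64)
    for s in range(n):
        c = eligible[rng.integers(len(eligible))]
        pair = rng.choice(members[c], size=2, replace=False)
        while True:
            odd = rng.integers(len(labels))
            if inverse[odd] != c:
                break
        out[s] = (pair[0], pair[1], odd)
    return out


def sample_class_boundary_triplets(
    labels: Sequence[int] | np.ndarray, n: int, seed: int = 0
) -> np.ndarray:
    """Triplets with two items from one class and one from another.

    The same-class pair occupies positions (i, j); the odd item is k.  The
    class of the pair is uniform over classes with >= 2 members; the odd
    item is uniform over all items outside that class.
    """
    return _boundary_from_labels(np.asarray(labels), n, np.random.default_rng(seed))


def cluster_representations(Z: np.ndarray, c: int, seed: int = 0, n_init: int = 5) -> ClusterAssignment:
    """Seeded k-means over representation rows (best of ``n_init`` restarts)."""
    Z = np.asarray(Z, dtype=float)
    if c < 2 or c > Z.shape[0]:
        raise ValueError(f"c must be in [2, n_items], got {c}")
    km = KMeans(n_clusters=c, n_init=n_init, random_state=seed).fit(Z)
    return ClusterAssignment(labels=km.labels_, n_clusters=c, inertia=float(km.inertia_))


def select_k_elbow(
    Z: np.ndarray, candidate_cs: Sequence[int], seed: int = 0, min_curvature: float = 1e-8
) -> int:
    """Pick the cluster count at the knee of the inertia curve.

    The knee is the interior candidate maximizing the discrete second
    difference of inertia.  If no candidate has positive curvature above
    ``min_curvature`` (featureless data), fall back to the smallest
    candidate with a warning.
    """
    cs = list(candidate_cs)
    if len(cs) < 3:
        raise ValueError("need at least 3 candidate cluster counts")
    if any(b <= a for a, b in zip(cs, cs[1:])):
        raise ValueError("candidates must be sorted strictly ascending")
    inertias = np.array([cluster_representations(Z, c, seed=seed).inertia for c in cs])
    curvature = inertias[:-2] - 2 * inertias[1:-1] + inertias[2:]
    if curvature.max() <= min_curvature:
        warnings.warn("inertia curve has no clear knee; falling back to smallest candidate")
        return cs[0]
    return cs[1 + int(np.argmax(curvature))]


def sample_cluster_boundary_triplets(
    assign: ClusterAssignment, n: int, seed: int = 0
) -> np.ndarray:
    """Boundary triplets using cluster ids in place of class labels."""
    return _boundary_from_labels(assign.labels, n, np.random.default_rng(seed))


def sample_levels_triplets(
    superclass_map: Mapping[int, int] | np.ndarray,
    subclass_map: Mapping[int, int] | np.ndarray,
    level: str,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Stratified triplets at a requested abstraction level.

    ``coarse``: one item from each of three distinct superclasses (sampling
    uniform over superclasses, then one subclass, then an item).
    ``fine``: three items from a single subclass.
    ``boundary``: two items from one subclass, one from a subclass of a
    different superclass.
    """
    if level not in ("coarse", "fine", "boundary"):
        raise ValueError(f"unknown level {level!r}")
    sup = _as_label_array(superclass_map)
    sub = _as_label_array(subclass_map)
    if sup.shape != sub.shape:
        raise ValueError("superclass and subclass maps must cover the same items")
    # consistency: a subclass must not straddle superclasses
    for s in np.unique(sub):
        if len(np.unique(sup[sub == s])) != 1:
            raise ValueError(f"subclass {s} spans multiple superclasses")

    rng = np.random.default_rng(seed)
    supers = np.unique(sup)
    sub_of_super = {s: np.unique(sub[sup == s]) for s in supers}
    items_of_sub = {s: np.flatnonzero(sub == s) for s in np.unique(sub)}

    def pick_items(superclass: int, count: int) -> np.ndarray:
        candidates = [s for s in sub_of_super[superclass] if len(items_of_sub[s]) >= count]
        if not candidates:
            raise ValueError(f"superclass {superclass} has no subclass with >= {count} items")
        chosen_sub = candidates[rng.integers(len(candidates))]
        return rng.choice(items_of_sub[chosen_sub], size=count, replace=False)

    out = np.empty((n, 3), dtype=np.int64)
    if level == "coarse":
        if len(supers) < 3:
            raise ValueError("coarse triplets need >= 3 superclasses")
        for s in range(n):
            trio = rng.choice(supers, size=3, replace=False)
            out[s] = [pick_items(sc, 1)[0] for sc in trio]
    elif level == "fine":
        rich = [s for s in np.unique(sub) if len(items_of_sub[s]) >= 3]
        if not rich:
            raise ValueError("fine triplets need a subclass with >= 3 items")
        rich_supers = np.unique(sup[np.isin(sub, rich)])
        for s in range(n):
            sc = rich_supers[rng.integers(len(rich_supers))]
            out[s] = pick_items(sc, 3)
    else:  # boundary
        pair_supers = [s for s in supers if any(len(items_of_sub[x]) >= 2 for x in sub_of_super[s])]
        if not pair_supers or len(supers) < 2:
            raise ValueError("boundary triplets need 2 superclasses and a subclass with >= 2 items")
        for s in range(n):
            sc = pair_supers[rng.integers(len(pair_supers))]
            pair = pick_items(sc, 2)
            others = supers[supers != sc]
            odd_sc = others[rng.integers(len(others))]
            out[s] = [pair[0], pair[1], pick_items(odd_sc, 1)[0]]
    return out


def _as_label_array(m: Mapping[int, int] | np.ndarray) -> np.ndarray:
    if isinstance(m, Mapping):
        n = max(m) + 1
        arr = np.full(n, -1, dtype=np.int64)
        for k, v in m.items():
            arr[k] = v
        if np.any(arr < 0):
            raise ValueError("label map must cover items 0..max contiguously")
        return arr
    return np.asarray(m, dtype=np.int64)


def pseudolabel(
    teacher_space: np.ndarray, triplets: np.ndarray, temperature: float = 1.0
) -> PseudoLabelDataset:
    """Score triplets with the teacher's softmax pair distribution.

    ``teacher_space`` is expected to be the *transformed* teacher embedding
    (apply the affine alignment first).  The hard choice is the argmax of
    the soft distribution, ties resolved by fixed pair order.
    """
    sims = batch_pair_similarities(np.asarray(teacher_space, dtype=float), triplets)
    soft = batch_choice_probabilities(sims, temperature)
    return PseudoLabelDataset(
        triplets=np.asarray(triplets, dtype=np.int64),
        teacher_soft=soft,
        teacher_choice=np.argmax(soft, axis=1),
    )
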