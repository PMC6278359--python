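"""Euclidean distance model and neighbor-composition analyses.

The distance model is the geometric substrate of every rivality statistic:
a symmetric Euclidean distance matrix on the range-scaled descriptor
matrix, with the diagonal set to +Inf so a molecule is never its own
neighbor, and per-molecule neighbor lists sorted by ascending distance.
Ties are broken by ascending original row index, which makes every
downstream quantity deterministic across platforms.

Rank positions are 1-based throughout ("first nearest neighbor" is
position 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistanceModel",
    "NeighborComposition",
    "build_distance_model",
    "first_neighbor",
    "nth_same_class_ordinal",
    "diffclass_before_nth",
    "cliff_pair_table",
]


@dataclass(frozen=True)
class DistanceModel:
    """Pairwise Euclidean distances with Inf diagonal and sorted neighbor lists.

    Attributes
    ----------
    distances : ndarray, shape (n, n)
        Symmetric; ``distances[i, i] = +inf``.
    rank_lists : ndarray, shape (n, n-1)
        ``rank_lists[i]`` is every j != i sorted by ascending distance to i,
        ties broken by ascending row index.
    """

    distances: np.ndarray
    rank_lists: np.ndarray

    @property
    def n_molecules(self) -> int:
        return self.distances.shape[0]

    def pairwise_sd(self) -> float:
        """Standard deviation of all finite pairwise distances (i < j).

        This is the default activity-border threshold.
        """
        iu = np.triu_indices(self.n_molecules, k=1)
        return float(np.std(self.distances[iu]))


@dataclass(frozen=True)
class NeighborComposition:
    """Different-class intrusion into a molecule's same-class neighbor window.

    ``window = (tn_low, tn_high)`` are ordinals of same-class neighbors; the
    composition counts different-class molecules ranked after the
    (tn_low - 1)-th same-class neighbor and before the tn_high-th one.
    ``offending_pairs`` lists each as ``(molecule_index, intruder_index)``.
    """

    molecule: int
    window: tuple
    diffclass_count: int
    offending_pairs: tuple


def build_distance_model(ds) -> DistanceModel:
    """Build the distance model from a scaled, cleaned dataset."""
    if not ds.scaled:
        raise ValueError("build_distance_model requires a scaled dataset")
    X = ds.values()
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 molecules, got {n}")
    # row-wise sqrt-of-squared-sums; bit-identical to the distance computed
    # for an external molecule, so in-set and external RI agree exactly
    D = np.empty((n, n))
    for i in range(n):
        D[i] = np.sqrt(np.sum((X - X[i]) ** 2, axis=1))
    np.fill_diagonal(D, np.inf)
    # stable argsort on distances: equal distances keep ascending index order
    order = np.argsort(D, axis=1, kind="stable")
    rank_lists = order[:, : n - 1]  # the Inf self-entry sorts last
    return DistanceModel(distances=D, rank_lists=rank_lists)


def first_neighbor(model: DistanceModel, labels, i: int, same_class: bool):
    """Nearest neighbor of ``i`` restricted by class.

    Returns ``(distance, neighbor_index)`` for the closest j != i whose label
    equals (``same_class=True``) or differs from ``i``'s label.
    """
    labels = np.asarray(labels)
    for j in model.rank_lists[i]:
        match = labels[j] == labels[i]
        if match == same_class:
            return float(model.distances[i, j]), int(j)
    kind = "same" if same_class else "different"
    raise ValueError(f"molecule {i} has no {kind}-class neighbor")


def nth_same_class_ordinal(model: DistanceModel, labels, i: int, n: int) -> int:
    """1-based rank-list position of the n-th same-class neighbor of ``i``."""
    if n < 1:
        raise ValueError("ordinal must be >= 1")
    labels = np.asarray(labels)
    count = 0
    for pos, j in enumerate(model.rank_lists[i], start=1):
        if labels[j] == labels[i]:
            count += 1
            if count == n:
                return pos
    raise ValueError(
        f"molecule {i}: class has only {count} other member(s), ordinal {n} infeasible"
    )


def diffclass_before_nth(
    model: DistanceModel, labels, i: int, tn_low: int, tn_high: int
) -> NeighborComposition:
    """Different-class molecules inside a same-class neighbor window.

    Counts different-class molecules strictly closer than the ``tn_high``-th
    same-class neighbor of ``i`` and not closer than its ``tn_low - 1``-th
    (the full prefix when ``tn_low == 1``).  Molecules with a non-zero count
    at window (1, 1) are exactly the molecules whose nearest neighbor overall
    belongs to the other class — the activity-cliff signature.
    """
    if not (1 <= tn_low <= tn_high):
        raise ValueError("window must satisfy 1 <= tn_low <= tn_high")
    labels = np.asarray(labels)
    start_pos = 0 if tn_low == 1 else nth_same_class_ordinal(model, labels, i, tn_low - 1)
    end_pos = nth_same_class_ordinal(model, labels, i, tn_high)
    pairs = []
    for pos in range(start_pos + 1, end_pos):
        j = int(model.rank_lists[i][pos - 1])
        if labels[j] != labels[i]:
            pairs.append((i, j))
    return NeighborComposition(
        molecule=i,
        window=(tn_low, tn_high),
        diffclass_count=len(pairs),
        offending_pairs=tuple(pairs),
    )


def cliff_pair_table(model: DistanceModel, labels, window=(1, 1)):
    """Per-molecule neighbor compositions for one window, dataset-wide.

    The concatenated offending pairs identify "responsible" molecules: an
    intruder appearing in many molecules' windows is the neighbor driving
    those molecules toward positive rivality.
    """
    tn_low, tn_high = window
    return [
        diffclass_before_nth(model, labels, i, tn_low, tn_high)
        for i in range(model.n_molecules)
    ]
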