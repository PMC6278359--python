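"""Rivality index, weighted rivality, modelability (CMODI), cliffs and borders.

The rivality index of molecule *i* contrasts the distance to its nearest
same-class neighbor, ``d_x``, with the distance to its nearest
different-class neighbor, ``d_y``::

    RI_i = (d_x - d_y) / (d_x + d_y)

RI is in [-1, +1].  RI < 0 means the nearest relevant neighbor belongs to
*i*'s own class (the molecule is expected to be correctly classified by any
similarity-based model); RI > 0 flags an activity cliff — a molecule more
similar to the other class than to its own.  Two special cases: a genuine
tie ``d_x == d_y != 0`` gives RI = 0, while the fully degenerate
``d_x == d_y == 0`` (at least three coincident molecules of both classes)
is an 0/0 indetermination and is assigned the sentinel value -1e-6 so it
remains distinguishable from a true zero.

The *weighted* rivality index re-weights the two distances by the class
composition of the molecule's neighborhood::

    RI_i = (d_x * w_x - d_y * w_y) / (d_x * w_x + d_y * w_y)
    w_x = (CN - CN_x) / CN,   w_y = (CN - CN_y) / CN

where CN is the cardinality of the neighborhood: the length of the
shortest prefix of i's ascending neighbor list containing at least TN
(threshold of neighbors) molecules of each class, and CN_x / CN_y are the
same-/different-class counts inside that prefix.  A molecule surrounded by
the opposite class gets CN_x small, hence w_x large, pushing RI positive
even when d_x happens to be slightly smaller than d_y.

CMODI, the dataset modelability index, is the unweighted mean over classes
of the fraction of each class's molecules with RI <= 0.  It is a
model-free forecast of the correct classification rate (balanced accuracy)
attainable by similarity-based classifiers; with the plain (TN-free) index
it equals the leave-one-out 1-nearest-neighbor balanced accuracy exactly
on tie-free data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neighbors import DistanceModel, build_distance_model, first_neighbor

__all__ = [
    "SENTINEL",
    "NeighborhoodProfile",
    "rivality_plain",
    "neighborhood_profile",
    "rivality_weighted",
    "rivality_against",
    "rivality_profile",
    "cmodi",
    "detect_cliffs",
    "detect_borders",
    "RivalityModel",
    "RivalityResults",
]

#: Sentinel assigned to the 0/0 indetermination (d_x = d_y = 0).
SENTINEL = -1e-6


@dataclass(frozen=True)
class NeighborhoodProfile:
    """Neighborhood cardinality and class weights of one molecule at one TN."""

    molecule: int
    tn: int
    cn: int
    cn_x: int
    cn_y: int
    w_x: float
    w_y: float


def _ri_core(a: float, b: float):
    """(a - b)/(a + b) with the tie and 0/0 special cases.

    Returns ``(value, sentinel_flag)``.
    """
    if a == b:
        if a == 0.0:
            return SENTINEL, True
        return 0.0, False
    return (a - b) / (a + b), False


def rivality_plain(d_x: float, d_y: float, with_flag: bool = False):
    """Plain (first-neighbor) rivality index from the two distances.

    Parameters
    ----------
    d_x, d_y : float
        Distance to the nearest same-class / different-class neighbor.
        Must be finite and non-negative.
    with_flag : bool
        If true, return ``(ri, sentinel_flag)`` instead of just the value.
    """
    for name, d in (("d_x", d_x), ("d_y", d_y)):
        if not np.isfinite(d) or d < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {d}")
    ri, flag = _ri_core(float(d_x), float(d_y))
    return (ri, flag) if with_flag else ri


def _profile_from_ranked(ranked_labels, own_label, tn: int):
    """CN, CN_x, CN_y from an ascending-distance label sequence.

    The prefix rule: CN is the length of the shortest prefix holding >= tn
    labels equal to ``own_label`` and >= tn different ones.
    """
    n_same = n_diff = 0
    for pos, lab in enumerate(ranked_labels, start=1):
        if lab == own_label:
            n_same += 1
        else:
            n_diff += 1
        if n_same >= tn and n_diff >= tn:
            return pos, n_same, n_diff
    raise ValueError(
        f"threshold of neighbors TN={tn} infeasible: only {n_same} same-class and "
        f"{n_diff} different-class neighbors available"
    )


def neighborhood_profile(model: DistanceModel, labels, i: int, tn: int) -> NeighborhoodProfile:
    """Neighborhood cardinality and weights of molecule ``i`` at threshold ``tn``."""
    if tn < 1:
        raise ValueError("TN must be >= 1")
    labels = np.asarray(labels)
    ranked = labels[model.rank_lists[i]]
    try:
        cn, cn_x, cn_y = _profile_from_ranked(ranked, labels[i], tn)
    except ValueError as exc:
        raise ValueError(f"molecule {i}: {exc}") from exc
    return NeighborhoodProfile(
        molecule=i,
        tn=tn,
        cn=cn,
        cn_x=cn_x,
        cn_y=cn_y,
        w_x=(cn - cn_x) / cn,
        w_y=(cn - cn_y) / cn,
    )


def rivality_weighted(model: DistanceModel, labels, i: int, tn: int, with_flag: bool = False):
    """Neighborhood-weighted rivality index of molecule ``i`` at threshold ``tn``."""
    prof = neighborhood_profile(model, labels, i, tn)
    d_x, _ = first_neighbor(model, labels, i, same_class=True)
    d_y, _ = first_neighbor(model, labels, i, same_class=False)
    ri, flag = _ri_core(d_x * prof.w_x, d_y * prof.w_y)
    return (ri, flag) if with_flag else ri


def rivality_against(dist_vector, cand_labels, own_label, tn: int = 0):
    """Rivality of one molecule against an arbitrary reference set.

    This is the single primitive behind both the in-set index (the reference
    set is the rest of the dataset) and the external applicability-domain
    index (the reference set is the training set).  Ties in distance are
    broken by ascending reference index.

    Parameters
    ----------
    dist_vector : array
        Distances from the molecule to every reference molecule (entries of
        +inf are skipped, which is how a molecule is excluded from its own
        reference set).
    cand_labels : array
        Class label of every reference molecule.
    own_label :
        Class label of the molecule itself.
    tn : int
        Threshold of neighbors; 0 selects the plain first-neighbor index.

    Returns
    -------
    (ri, sentinel_flag, detail) where detail is a dict with d_x, d_y, the
    neighbor indices, and (for tn >= 1) cn/cn_x/cn_y/w_x/w_y.
    """
    dist_vector = np.asarray(dist_vector, dtype=float)
    cand_labels = np.asarray(cand_labels)
    order = np.argsort(dist_vector, kind="stable")
    order = order[np.isfinite(dist_vector[order])]
    same_mask = cand_labels[order] == own_label
    same_pos = np.flatnonzero(same_mask)
    diff_pos = np.flatnonzero(~same_mask)
    if same_pos.size == 0 or diff_pos.size == 0:
        raise ValueError("reference set must contain both same- and different-class molecules")
    x = int(order[same_pos[0]])
    y = int(order[diff_pos[0]])
    d_x = float(dist_vector[x])
    d_y = float(dist_vector[y])
    detail = {"d_x": d_x, "d_y": d_y, "neighbor_same": x, "neighbor_diff": y}
    if tn == 0:
        ri, flag = _ri_core(d_x, d_y)
        return ri, flag, detail
    cn, cn_x, cn_y = _profile_from_ranked(cand_labels[order], own_label, tn)
    w_x = (cn - cn_x) / cn
    w_y = (cn - cn_y) / cn
    detail.update(cn=cn, cn_x=cn_x, cn_y=cn_y, w_x=w_x, w_y=w_y)
    ri, flag = _ri_core(d_x * w_x, d_y * w_y)
    return ri, flag, detail


def rivality_profile(model: DistanceModel, labels, tn_list):
    """RI of every molecule at every requested TN.

    TN = 0 denotes the plain first-neighbor index.  Returns
    ``(ri_matrix, sentinel_matrix)`` of shape (n_molecules, len(tn_list)).
    """
    labels = np.asarray(labels)
    n = model.n_molecules
    ri = np.empty((n, len(tn_list)))
    sent = np.zeros((n, len(tn_list)), dtype=bool)
    for i in range(n):
        for k, tn in enumerate(tn_list):
            ri[i, k], sent[i, k], _ = rivality_against(
                model.distances[i], labels, labels[i], tn=tn
            )
    return ri, sent


def cmodi(ris, labels, sentinel=None):
    """Per-class modelability and CMODI from one RI per molecule.

    A molecule counts as correctly classifiable when RI <= 0 (the sentinel
    -1e-6 is negative, so indeterminate molecules count too).  Per-class
    modelability is the classifiable fraction of each class; CMODI is their
    unweighted mean — balanced over classes regardless of class sizes.
    """
    ris = np.asarray(ris, dtype=float)
    labels = np.asarray(labels)
    if len(ris) != len(labels):
        raise ValueError("need exactly one RI per molecule")
    per_class = {}
    for cls in np.unique(labels):
        mask = labels == cls
        per_class[cls] = float(np.mean(ris[mask] <= 0.0))
    return per_class, float(np.mean(list(per_class.values())))


def detect_cliffs(ris, sentinel=None):
    """Indices of activity cliffs: RI strictly > 0 (sentinels excluded)."""
    ris = np.asarray(ris, dtype=float)
    mask = ris > 0.0
    if sentinel is not None:
        mask &= ~np.asarray(sentinel, dtype=bool)
    return np.flatnonzero(mask)


def detect_borders(ris, threshold, sentinel=None):
    """Indices of activity borders: |RI| <= threshold, sentinels excluded.

    Borders are molecules whose classification outcome depends sensitively
    on training-set composition.  The conventional default threshold is the
    standard deviation of all pairwise scaled distances
    (:meth:`DistanceModel.pairwise_sd`); RI is dimensionless while that
    threshold is a distance, so treat it as a heuristic and override freely.
    """
    if threshold <= 0:
        raise ValueError("border threshold must be > 0")
    ris = np.asarray(ris, dtype=float)
    mask = np.abs(ris) <= threshold
    if sentinel is not None:
        mask &= ~np.asarray(sentinel, dtype=bool)
    return np.flatnonzero(mask)


class RivalityModel:
    """Rivality diagnostics of a descriptor dataset.

    Parameters
    ----------
    dataset : DescriptorDataset
        Cleaned, range-scaled dataset.
    distance_model : DistanceModel, optional
        Prebuilt distance model; computed from the dataset when omitted.

    Examples
    --------
    >>> model = RivalityModel(dataset)
    >>> res = model.fit(tn_list=(0, 1, 2, 3))
    >>> res.cmodi_[3], res.cliff_ids(3)
    """

    def __init__(self, dataset, distance_model: DistanceModel | None = None):
        if not dataset.scaled:
            raise ValueError("RivalityModel requires a range-scaled dataset")
        self.dataset = dataset
        self.distance_model = distance_model or build_distance_model(dataset)

    def fit(self, tn_list=(0, 1, 2, 3, 4, 5), border_threshold: float | None = None):
        """Compute RI at every TN in ``tn_list`` (0 = plain index).

        ``border_threshold`` defaults to the standard deviation of all
        pairwise scaled distances.
        """
        tn_list = tuple(int(t) for t in tn_list)
        if any(t < 0 for t in tn_list):
            raise ValueError("TN values must be >= 0")
        ri, sent = rivality_profile(self.distance_model, self.dataset.labels, tn_list)
        if border_threshold is None:
            border_threshold = self.distance_model.pairwise_sd()
        return RivalityResults(
            model=self,
            tn_list=tn_list,
            ri=ri,
            sentinel=sent,
            border_threshold=float(border_threshold),
        )


class RivalityResults:
    """Fitted rivality diagnostics: RI matrix, CMODI, cliffs and borders.

    Attributes
    ----------
    ri_ : pandas.DataFrame
        Molecules x TN rivality matrix (column 0 = plain index when requested).
    sentinel_ : pandas.DataFrame
        Boolean flags for 0/0-indeterminate entries.
    cmodi_ : pandas.Series
        CMODI per TN.
    per_class_modelability_ : pandas.DataFrame
        Classes x TN classifiable fractions.
    border_threshold : float
    """

    def __init__(self, model, tn_list, ri, sentinel, border_threshold):
        self.model = model
        self.tn_list = tn_list
        ids = list(model.dataset.molecule_ids)
        self.ri_ = pd.DataFrame(ri, index=ids, columns=list(tn_list))
        self.sentinel_ = pd.DataFrame(sentinel, index=ids, columns=list(tn_list))
        self.border_threshold = border_threshold
        labels = model.dataset.labels
        rows = {}
        cm = {}
        for tn in tn_list:
            per_class, overall = cmodi(self.ri_[tn].to_numpy(), labels)
            rows[tn] = per_class
            cm[tn] = overall
        self.per_class_modelability_ = pd.DataFrame(rows)
        self.cmodi_ = pd.Series(cm, name="CMODI")

    @property
    def molecule_ids(self):
        return list(self.ri_.index)

    def _col(self, tn):
        if tn not in self.ri_.columns:
            raise KeyError(f"TN={tn} was not fitted (fitted: {list(self.ri_.columns)})")
        return self.ri_[tn].to_numpy(), self.sentinel_[tn].to_numpy()

    def cliffs(self, tn) -> np.ndarray:
        """Positional indices of activity cliffs (RI > 0) at one TN."""
        ri, sent = self._col(tn)
        return detect_cliffs(ri, sent)

    def cliff_ids(self, tn) -> list:
        return [self.molecule_ids[i] for i in self.cliffs(tn)]

    def borders(self, tn, threshold: float | None = None) -> np.ndarray:
        """Positional indices of activity borders at one TN."""
        ri, sent = self._col(tn)
        if threshold is None:
            threshold = self.border_threshold
        return detect_borders(ri, threshold, sent)

    def border_ids(self, tn, threshold: float | None = None) -> list:
        return [self.molecule_ids[i] for i in self.borders(tn, threshold)]

    def summary(self) -> str:
        """Plain-text summary table: per-TN CMODI, class modelability, counts."""
        ds = self.model.dataset
        classes = list(ds.classes)
        lines = [
            "Rivality diagnostics",
            "=" * 66,
            f"molecules: {ds.n_molecules}   descriptors: {ds.n_features}   "
            f"classes: {len(classes)}",
            f"border threshold: {self.border_threshold:.4f} "
            "(sd of pairwise scaled distances)",
            "-" * 66,
            f"{'TN':>5} {'CMODI':>8} "
            + " ".join(f"{'M[' + str(c) + ']':>8}" for c in classes)
            + f" {'cliffs':>7} {'borders':>8}",
        ]
        for tn in self.tn_list:
            tag = "plain" if tn == 0 else str(tn)
            per_class = self.per_class_modelability_[tn]
            lines.append(
                f"{tag:>5} {self.cmodi_[tn]:8.3f} "
                + " ".join(f"{per_class[c]:8.3f}" for c in classes)
                + f" {len(self.cliffs(tn)):7d} {len(self.borders(tn)):8d}"
            )
        lines.append("=" * 66)
        lines.append("TN 'plain' = first-neighbor index; cliffs: RI > 0; "
                     "borders: |RI| <= threshold")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Wide per-molecule table: label, RI per TN, cliff/border flags."""
        ds = self.model.dataset
        df = pd.DataFrame({"label": ds.labels}, index=self.ri_.index)
        for tn in self.tn_list:
            name = "RI_plain" if tn == 0 else f"RI_TN{tn}"
            df[name] = self.ri_[tn]
        ref_tn = self.tn_list[-1]
        cliff_idx = set(self.cliffs(ref_tn))
        border_idx = set(self.borders(ref_tn))
        df["cliff"] = [i in cliff_idx for i in range(len(df))]
        df["border"] = [i in border_idx for i in range(len(df))]
        return df
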