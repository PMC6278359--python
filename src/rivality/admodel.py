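"""Applicability-domain assessment of external molecules and dataset curation.

The applicability domain (AD) question — "can a model built on this
training set be trusted on that new molecule?" — is answered here without
building any model: each external molecule is added, one at a time, to the
training context and its rivality index is computed against the training
molecules only.  RI > 0 means the molecule sits closer to the wrong class
in the training descriptor space (outside the AD); a strongly negative RI
means the molecule is embedded in its own class's neighborhood (inside);
|RI| below the border threshold marks the uncertain border zone.

Test molecules never see each other: the RI of one external molecule is
invariant to the composition of the rest of the test set.

Cliff erasure (:func:`erase_cliffs`) is the complementary curation step:
removing the training molecules with RI > 0 removes the noise that
similarity-based learners cannot fit, typically raising the modelability
of the remaining set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .benchmark import ClassificationStats, classification_stats
from .io import DescriptorDataset, apply_scale
from .model import RivalityModel, rivality_against
from .neighbors import DistanceModel, build_distance_model

__all__ = [
    "ADReport",
    "ApplicabilityDomain",
    "external_rivality",
    "ad_assess",
    "erase_cliffs",
    "split_dataset",
]


def external_rivality(train_ds, test_vector, test_label, tn: int = 0):
    """Rivality index of one external molecule against a training set.

    Distances run from the test molecule to every training molecule only.
    Returns ``(ri, sentinel_flag, detail)`` with the nearest same-/different-
    class training neighbors and distances in ``detail``.
    """
    X = train_ds.values()
    v = np.asarray(test_vector, dtype=float)
    if v.shape != (X.shape[1],):
        raise ValueError(
            f"test vector has {v.shape} values, training set has {X.shape[1]} columns"
        )
    dists = np.sqrt(np.sum((X - v) ** 2, axis=1))
    return rivality_against(dists, train_ds.labels, test_label, tn=tn)


@dataclass(frozen=True)
class ADReport:
    """Per-molecule AD assessment of an external set plus aggregates.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per test molecule: RI per TN, verdict, nearest training
        neighbors and distances, out-of-descriptor-range flag.
    stats : dict
        TN -> ClassificationStats of the RI-based correctness predictions.
    cmodi : pandas.Series
        Test-set CMODI per TN.
    per_class_modelability : pandas.DataFrame
        Classes x TN classifiable fractions of the test set.
    border_threshold : float
    verdict_tn : int
        The TN whose RI determined the verdict column.
    """

    table: pd.DataFrame
    stats: dict
    cmodi: pd.Series
    per_class_modelability: pd.DataFrame
    border_threshold: float
    verdict_tn: int


class ApplicabilityDomain:
    """AD assessor bound to one (scaled) training set.

    Parameters
    ----------
    train : DescriptorDataset
        Cleaned, range-scaled training set; its ``scale_params`` are used to
        scale incoming external molecules ("train" scaling mode).
    """

    def __init__(self, train: DescriptorDataset):
        if not train.scaled:
            raise ValueError("ApplicabilityDomain requires a scaled training set")
        self.train = train
        self.distance_model: DistanceModel = build_distance_model(train)

    def assess(
        self,
        test_features,
        test_labels,
        test_ids=None,
        tn_list=(0, 1, 2, 3),
        border_threshold: float | None = None,
        verdict_tn: int | None = None,
        prescaled: bool = False,
    ) -> ADReport:
        """Assess an external set molecule by molecule.

        ``test_features`` may be a DataFrame or array over the training
        columns.  Unless ``prescaled``, values are scaled with the training
        set's per-column (min, max); values landing outside [0, 1] set the
        out-of-range flag (the molecule leaves the training descriptor box).
        """
        feats = pd.DataFrame(test_features)
        if isinstance(test_features, pd.DataFrame):
            missing = [c for c in self.train.features.columns if c not in feats.columns]
            if missing:
                raise ValueError(f"test set lacks training columns: {missing}")
            feats = feats[list(self.train.features.columns)]
        else:
            feats.columns = list(self.train.features.columns)
        labels = np.asarray(test_labels)
        if len(feats) == 0:
            raise ValueError("empty test set")
        if len(feats) != len(labels):
            raise ValueError("one label per test molecule required")
        if test_ids is None:
            test_ids = [f"test_{k}" for k in range(len(feats))]

        X = feats.to_numpy(dtype=float)
        if not prescaled:
            lo = np.array([self.train.scale_params[c][0] for c in feats.columns])
            hi = np.array([self.train.scale_params[c][1] for c in feats.columns])
            X = (X - lo) / (hi - lo)
        out_of_range = np.any((X < 0.0) | (X > 1.0), axis=1)

        tn_list = tuple(int(t) for t in tn_list)
        if verdict_tn is None:
            verdict_tn = tn_list[-1]
        if border_threshold is None:
            border_threshold = self.distance_model.pairwise_sd()

        rows = []
        ri_mat = np.empty((len(X), len(tn_list)))
        sent_mat = np.zeros_like(ri_mat, dtype=bool)
        for k, v in enumerate(X):
            row = {"id": test_ids[k], "label": labels[k],
                   "out_of_range": bool(out_of_range[k])}
            for c, tn in enumerate(tn_list):
                ri, flag, detail = external_rivality(self.train, v, labels[k], tn=tn)
                ri_mat[k, c] = ri
                sent_mat[k, c] = flag
                name = "RI_plain" if tn == 0 else f"RI_TN{tn}"
                row[name] = ri
                if tn == verdict_tn:
                    row["d_x"] = detail["d_x"]
                    row["d_y"] = detail["d_y"]
                    row["nn_same"] = self.train.molecule_ids[detail["neighbor_same"]]
                    row["nn_diff"] = self.train.molecule_ids[detail["neighbor_diff"]]
            rows.append(row)

        v_col = list(tn_list).index(verdict_tn)
        verdicts = []
        for k in range(len(X)):
            ri = ri_mat[k, v_col]
            if ri > 0:
                verdicts.append("outside")
            elif abs(ri) <= border_threshold and not sent_mat[k, v_col]:
                verdicts.append("border")
            else:
                verdicts.append("inside")
        table = pd.DataFrame(rows).set_index("id")
        table["verdict"] = verdicts

        from .model import cmodi as _cmodi  # noqa: PLC0415 — avoid cycle at import

        stats = {}
        cm = {}
        pcm = {}
        for c, tn in enumerate(tn_list):
            per_class, overall = _cmodi(ri_mat[:, c], labels)
            cm[tn] = overall
            pcm[tn] = per_class
            stats[tn] = _stats_from_correctness(
                labels, ri_mat[:, c] <= 0.0, all_classes=self.train.classes
            )
        return ADReport(
            table=table,
            stats=stats,
            cmodi=pd.Series(cm, name="CMODI"),
            per_class_modelability=pd.DataFrame(pcm),
            border_threshold=float(border_threshold),
            verdict_tn=verdict_tn,
        )


def _stats_from_correctness(labels, correct, sensitivity_class=None,
                            all_classes=None) -> ClassificationStats:
    """ClassificationStats where 'predicted right' means RI <= 0.

    For a binary problem the implied prediction is the true label when the
    molecule is classifiable and the other label otherwise, which makes SE
    and SP coincide with the per-class modelabilities.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels) if all_classes is None else np.asarray(all_classes)
    preds = labels.copy()
    wrong = ~np.asarray(correct, dtype=bool)
    for idx in np.flatnonzero(wrong):
        others = classes[classes != labels[idx]]
        preds[idx] = others[0]
    return classification_stats(labels, preds, sensitivity_class)


def ad_assess(train, test_features, test_labels, test_ids=None, **kwargs) -> ADReport:
    """Functional wrapper over :meth:`ApplicabilityDomain.assess`."""
    return ApplicabilityDomain(train).assess(test_features, test_labels, test_ids, **kwargs)


def erase_cliffs(ds: DescriptorDataset, tn: int, distance_model=None):
    """Remove the activity cliffs (RI > 0 at ``tn``) from a dataset.

    Returns ``(curated_dataset, removed_ids)``.  The caller must rebuild the
    distance model: survivors' neighborhoods — and hence their RIs — change
    once the cliffs are gone.  Raises if erasure would leave any class with
    fewer than 2 molecules.
    """
    res = RivalityModel(ds, distance_model).fit(tn_list=(tn,))
    cliff_idx = res.cliffs(tn)
    removed = [ds.molecule_ids[i] for i in cliff_idx]
    keep = np.setdiff1d(np.arange(ds.n_molecules), cliff_idx)
    labels_kept = np.asarray(ds.labels)[keep]
    for cls in ds.classes:
        if np.sum(labels_kept == cls) < 2:
            raise ValueError(
                f"erasing cliffs would leave class {cls!r} with < 2 molecules"
            )
    return ds.subset(keep), removed


def split_dataset(ds: DescriptorDataset, fraction: float = 0.8, seed: int = 0):
    """Stratified random train/test split; returns ``(train_ids, test_ids)``.

    Per class, ``round(fraction * class_size)`` molecules go to training
    (at least 1 per class in each part).  Deterministic given the seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.asarray(ds.labels)
    train_idx, test_idx = [], []
    for cls in ds.classes:
        members = np.flatnonzero(labels == cls)
        n_train = int(round(fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        perm = rng.permutation(members)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    train_idx.sort()
    test_idx.sort()
    return (
        [ds.molecule_ids[i] for i in train_idx],
        [ds.molecule_ids[i] for i in test_idx],
    )
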