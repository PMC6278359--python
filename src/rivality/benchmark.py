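"""Random-Forest / linear-SVM comparison harness.

The rivality framework forecasts, without building any model, which
molecules a similarity-based classifier will misclassify.  This module
provides the classifiers to compare against: a Random Forest (bagged
decision trees) and a linear-kernel SVM, evaluated by leave-one-out,
repeated stratified 5-fold cross-validation, or a single external
validation, all with library-default hyperparameters.

Statistics follow the binary-QSAR convention: SE (sensitivity) is the
recall of the designated sensitivity class (by default the first class in
sorted label order, conventionally "0"), SP (specificity) the recall of
the other class, ACC the overall fraction correct, and CCR the balanced
accuracy (SE + SP) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ClassificationStats",
    "ModelRun",
    "classification_stats",
    "make_classifier",
    "evaluate_loo",
    "evaluate_cv",
    "evaluate_external",
    "compare_outliers",
]


@dataclass(frozen=True)
class ClassificationStats:
    """Confusion counts and SE/SP/ACC/CCR for one prediction set."""

    per_class: dict  # class -> (n_correct, n_total)
    se: float
    sp: float
    acc: float
    ccr: float
    sensitivity_class: object


@dataclass(frozen=True)
class ModelRun:
    """One evaluated classifier: predictions, outliers, statistics."""

    algorithm: str
    protocol: str
    seed: int | None
    predictions: np.ndarray
    truth: np.ndarray
    outliers: np.ndarray  # positional indices with prediction != truth
    stats: ClassificationStats
    repeat: int = 0
    molecule_ids: tuple = field(default=())


def classification_stats(truth, predicted, sensitivity_class=None) -> ClassificationStats:
    """SE, SP, ACC and CCR from true and predicted labels.

    For a two-class problem SE is the recall of ``sensitivity_class``
    (default: first class in sorted order) and SP the recall of the other
    class.  A class absent from ``truth`` yields NaN recall and propagates
    NaN into CCR — degenerate single-class evaluation sets are flagged, not
    silently averaged away.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have the same length")
    classes = np.unique(truth)
    all_classes = np.unique(np.concatenate([truth, predicted]))
    if sensitivity_class is None:
        sensitivity_class = np.sort(all_classes)[0]
    per_class = {}
    recalls = {}
    for cls in all_classes:
        mask = truth == cls
        total = int(mask.sum())
        correct = int(np.sum(predicted[mask] == cls))
        per_class[cls] = (correct, total)
        recalls[cls] = correct / total if total else float("nan")
    se = recalls.get(sensitivity_class, float("nan"))
    others = [r for c, r in recalls.items() if c != sensitivity_class]
    sp = others[0] if len(others) == 1 else float(np.mean(others)) if others else float("nan")
    acc = float(np.mean(predicted == truth))
    ccr = (se + sp) / 2.0
    if len(classes) < 2:
        se, sp, ccr = (se, sp, float("nan")) if np.isnan(se) or np.isnan(sp) else (se, sp, ccr)
    return ClassificationStats(
        per_class=per_class,
        se=float(se),
        sp=float(sp),
        acc=acc,
        ccr=float(ccr),
        sensitivity_class=sensitivity_class,
    )


def make_classifier(algorithm: str, seed: int | None = None):
    """Instantiate one of the two benchmark classifiers with defaults."""
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed)
    if algorithm == "svm":
        return SVC(kernel="linear", random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r} (expected 'rf' or 'svm')")


def evaluate_loo(algorithm: str, ds, seed: int | None = 0,
                 sensitivity_class=None) -> ModelRun:
    """Leave-one-out evaluation: each molecule predicted by a model on the rest."""
    X = ds.values()
    y = np.asarray(ds.labels)
    n = len(y)
    preds = np.empty(n, dtype=y.dtype)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"leaving out molecule {i} empties a class")
        clf = make_classifier(algorithm, seed)
        clf.fit(X[train], y[train])
        preds[i] = clf.predict(X[i : i + 1])[0]
    outliers = np.flatnonzero(preds != y)
    return ModelRun(
        algorithm=algorithm,
        protocol="loo",
        seed=seed,
        predictions=preds,
        truth=y,
        outliers=outliers,
        stats=classification_stats(y, preds, sensitivity_class),
        molecule_ids=tuple(ds.molecule_ids),
    )


def evaluate_cv(algorithm: str, ds, folds: int = 5, repeats: int = 5,
                seed: int = 0, sensitivity_class=None) -> list[ModelRun]:
    """Repeated stratified k-fold cross-validation; one ModelRun per repeat."""
    X = ds.values()
    y = np.asarray(ds.labels)
    runs = []
    for r in range(repeats):
        rep_seed = seed + r
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        preds = np.empty(len(y), dtype=y.dtype)
        for train, test in skf.split(X, y):
            clf = make_classifier(algorithm, rep_seed)
            clf.fit(X[train], y[train])
            preds[test] = clf.predict(X[test])
        outliers = np.flatnonzero(preds != y)
        runs.append(
            ModelRun(
                algorithm=algorithm,
                protocol=f"cv{folds}",
                seed=rep_seed,
                predictions=preds,
                truth=y,
                outliers=outliers,
                stats=classification_stats(y, preds, sensitivity_class),
                repeat=r,
                molecule_ids=tuple(ds.molecule_ids),
            )
        )
    return runs


def evaluate_external(algorithm: str, train_ds, test_ds, seed: int | None = 0,
                      sensitivity_class=None) -> ModelRun:
    """Fit once on the training set, predict the external test set."""
    if list(train_ds.features.columns) != list(test_ds.features.columns):
        raise ValueError("train and test descriptor columns differ")
    overlap = set(train_ds.molecule_ids) & set(test_ds.molecule_ids)
    if overlap:
        raise ValueError(f"train/test id overlap: {sorted(overlap)[:5]}")
    clf = make_classifier(algorithm, seed)
    clf.fit(train_ds.values(), np.asarray(train_ds.labels))
    y = np.asarray(test_ds.labels)
    preds = clf.predict(test_ds.values())
    outliers = np.flatnonzero(preds != y)
    return ModelRun(
        algorithm=algorithm,
        protocol="external",
        seed=seed,
        predictions=preds,
        truth=y,
        outliers=outliers,
        stats=classification_stats(y, preds, sensitivity_class),
        molecule_ids=tuple(test_ds.molecule_ids),
    )


def compare_outliers(run: ModelRun, results, tn) -> dict:
    """Cross-tabulate a classifier's outliers against rivality cliffs.

    Returns per-molecule agreement, the Jaccard index of the two sets, and
    the discordant molecules annotated with their activity-border status
    (border molecules are where classifier and index legitimately differ).
    """
    ids = list(run.molecule_ids)
    if ids != results.molecule_ids:
        raise ValueError("ModelRun and RivalityResults cover different molecules")
    outlier_set = {ids[i] for i in run.outliers}
    cliff_set = set(results.cliff_ids(tn))
    border_set = set(results.border_ids(tn))
    union = outlier_set | cliff_set
    inter = outlier_set & cliff_set
    jaccard = len(inter) / len(union) if union else 1.0
    discordant = [
        {"id": m, "outlier": m in outlier_set, "cliff": m in cliff_set,
         "border": m in border_set}
        for m in sorted(union - inter)
    ]
    return {
        "jaccard": jaccard,
        "n_outliers": len(outlier_set),
        "n_cliffs": len(cliff_set),
        "agree": sorted(inter),
        "discordant": discordant,
    }
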