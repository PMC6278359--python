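"""Descriptor-table I/O, validation, cleaning, and range scaling.

A QSAR classification dataset is a table with one row per molecule: a
molecule identifier, a class label (binary in the canonical use case,
but any number of classes >= 2 is accepted), and numeric descriptor
columns.  All distance-based statistics downstream operate on the
range-scaled matrix, so the pipeline is always

    read_descriptor_table -> clean_columns -> range_scale

External (test) molecules are scaled with the *training* set's per-column
parameters via :func:`apply_scale`, so that a molecule outside the
training descriptor ranges is visible as a value outside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorDataset",
    "read_descriptor_table",
    "clean_columns",
    "range_scale",
    "apply_scale",
    "write_descriptor_table",
]


@dataclass(frozen=True)
class DescriptorDataset:
    """An immutable descriptor table with ids, class labels and features.

    Parameters
    ----------
    molecule_ids : tuple of str
        Unique identifiers, in row order.
    labels : numpy.ndarray
        One class label per molecule (opaque categories; compared with ``==``).
    features : pandas.DataFrame
        Numeric descriptor matrix, one named column per descriptor.
    scaled : bool
        True once Max/Min range scaling has been applied.
    scale_params : dict
        Per-column ``(min, max)`` recorded at scaling time; empty until scaled.
    """

    molecule_ids: tuple
    labels: np.ndarray
    features: pd.DataFrame
    scaled: bool = False
    scale_params: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = list(self.molecule_ids)
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate molecule id: {dup!r}")
        if len(ids) != len(self.labels) or len(ids) != len(self.features):
            raise ValueError("ids, labels and features must have equal length")
        classes, counts = np.unique(np.asarray(self.labels), return_counts=True)
        if len(classes) < 2:
            raise ValueError("dataset must contain at least 2 classes")
        for cls, cnt in zip(classes, counts):
            if cnt < 2:
                raise ValueError(
                    f"class {cls!r} has {cnt} member(s); every class needs >= 2 "
                    "(the nearest same-class neighbor must exist for every molecule)"
                )
        if self.scaled:
            vals = self.features.to_numpy(dtype=float)
            if not self.scale_params:
                raise ValueError("scaled dataset must carry scale_params")
            if vals.size and (np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12):
                raise ValueError("scaled dataset has values outside [0, 1]")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Distinct class labels in sorted order."""
        return np.unique(np.asarray(self.labels))

    def values(self) -> np.ndarray:
        """Feature matrix as a float ndarray (n_molecules x n_features)."""
        return self.features.to_numpy(dtype=float)

    def subset(self, indices) -> "DescriptorDataset":
        """Row subset by positional indices, preserving scaling state."""
        indices = np.asarray(indices)
        return DescriptorDataset(
            molecule_ids=tuple(self.molecule_ids[i] for i in indices),
            labels=np.asarray(self.labels)[indices],
            features=self.features.iloc[indices].reset_index(drop=True),
            scaled=self.scaled,
            scale_params=dict(self.scale_params),
        )

    def index_of(self, molecule_id: str) -> int:
        return self.molecule_ids.index(molecule_id)


def read_descriptor_table(
    path,
    id_column: str = "id",
    label_column: str = "label",
    delimiter: str = ",",
) -> DescriptorDataset:
    """Read a delimited descriptor table into an unscaled dataset.

    Every column other than ``id_column`` and ``label_column`` must parse as
    numeric; NaN/Inf tokens are accepted here and removed later by
    :func:`clean_columns`.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={id_column: str},
                     float_precision="round_trip")
    for col in (id_column, label_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    feature_cols = [c for c in df.columns if c not in (id_column, label_column)]
    features = pd.DataFrame(index=df.index)
    for col in feature_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        # pd.to_numeric maps "inf"/"-inf" to +-Inf and "nan" to NaN; any cell
        # that became NaN without being a NaN token is a genuine parse error.
        bad = converted.isna() & df[col].notna() & ~df[col].astype(str).str.strip().str.lower().isin(
            ["nan", "+nan", "-nan"]
        )
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} at row {row}, column {col!r}"
            )
        features[col] = converted.astype(float)
    return DescriptorDataset(
        molecule_ids=tuple(df[id_column].tolist()),
        labels=df[label_column].to_numpy(),
        features=features,
    )


def clean_columns(ds: DescriptorDataset, report: bool = False):
    """Drop uninformative descriptor columns.

    Removes (a) any column containing NaN or +-Inf, (b) any all-zero column,
    and (c) any other constant column, for which Max/Min scaling would be
    undefined.  Idempotent.

    Returns the cleaned dataset, or ``(dataset, dropped)`` when ``report``
    is true, where ``dropped`` maps column name -> reason.
    """
    if ds.scaled:
        raise ValueError("clean_columns expects an unscaled dataset")
    dropped: dict = {}
    keep = []
    for col in ds.features.columns:
        vals = ds.features[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            dropped[col] = "contains NaN/Inf"
        elif np.all(vals == 0.0):
            dropped[col] = "all zero"
        elif vals.max() == vals.min():
            dropped[col] = "constant"
        else:
            keep.append(col)
    if not keep:
        raise ValueError("no informative descriptors remain after cleaning")
    out = replace(ds, features=ds.features[keep].copy())
    return (out, dropped) if report else out


def range_scale(ds: DescriptorDataset) -> DescriptorDataset:
    """Max/Min range scaling: each column mapped onto [0, 1].

    x -> (x - min) / (max - min), per column; the (min, max) pair is stored
    in ``scale_params`` so external molecules can be scaled consistently.
    """
    if ds.scaled:
        raise ValueError("dataset is already scaled")
    params = {}
    scaled = pd.DataFrame(index=ds.features.index)
    for col in ds.features.columns:
        vals = ds.features[col].to_numpy(dtype=float)
        lo, hi = float(vals.min()), float(vals.max())
        if hi == lo:
            raise ValueError(
                f"column {col!r} is constant; run clean_columns before range_scale"
            )
        scaled[col] = (vals - lo) / (hi - lo)
        params[col] = (lo, hi)
    return replace(ds, features=scaled, scaled=True, scale_params=params)


def apply_scale(ds: DescriptorDataset, scale_params: dict):
    """Scale a dataset with *given* (training-set) per-column parameters.

    Unlike :func:`range_scale` the result may contain values outside [0, 1]:
    such molecules lie outside the descriptor ranges of the training set.

    Returns ``(scaled_dataset, out_of_range)`` where ``out_of_range`` is a
    boolean array flagging molecules with any value outside [0, 1].
    """
    missing = [c for c in ds.features.columns if c not in scale_params]
    if missing:
        raise ValueError(f"scale_params missing columns: {missing}")
    scaled = pd.DataFrame(index=ds.features.index)
    for col in ds.features.columns:
        lo, hi = scale_params[col]
        scaled[col] = (ds.features[col].to_numpy(dtype=float) - lo) / (hi - lo)
    vals = scaled.to_numpy(dtype=float)
    out_of_range = np.any((vals < 0.0) | (vals > 1.0), axis=1)
    # bypass the frozen-dataclass [0,1] check: out-of-range is legal here
    out = DescriptorDataset.__new__(DescriptorDataset)
    object.__setattr__(out, "molecule_ids", ds.molecule_ids)
    object.__setattr__(out, "labels", ds.labels)
    object.__setattr__(out, "features", scaled)
    object.__setattr__(out, "scaled", True)
    object.__setattr__(out, "scale_params", dict(scale_params))
    return out, out_of_range


def write_descriptor_table(
    ds: DescriptorDataset,
    path,
    id_column: str = "id",
    label_column: str = "label",
    delimiter: str = ",",
) -> None:
    """Write a dataset back to delimited text (round-trips exactly)."""
    df = pd.DataFrame({id_column: list(ds.molecule_ids), label_column: ds.labels})
    for col in ds.features.columns:
        df[col] = ds.features[col].to_numpy()
    # shortest-unique float repr so a write/read cycle is value-exact
    df.to_csv(path, sep=delimiter, index=False,
              float_format=lambda x: repr(float(x)))
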