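"""Shared fixtures and the independent brute-force oracle.

The oracle re-derives every neighbor quantity with plain Python loops and
tuple sorting — no shared code with the package's vectorized path — so the
two implementations can check each other on random instances.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from rivality import DescriptorDataset


def make_dataset(values, labels, ids=None, scaled=True) -> DescriptorDataset:
    """Build a DescriptorDataset directly from an array (test convenience)."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n, d = values.shape
    if ids is None:
        ids = tuple(f"m{i}" for i in range(n))
    cols = [f"x{j}" for j in range(d)]
    return DescriptorDataset(
        molecule_ids=tuple(ids),
        labels=np.asarray(labels),
        features=pd.DataFrame(values, columns=cols),
        scaled=scaled,
        scale_params={c: (0.0, 1.0) for c in cols} if scaled else {},
    )


def random_dataset(rng, n=None, dim=None, min_per_class=2):
    """Random scaled dataset with both classes sufficiently populated."""
    n = n or int(rng.integers(2 * min_per_class + 2, 30))
    dim = dim or int(rng.integers(1, 6))
    values = rng.uniform(size=(n, dim))
    while True:
        labels = rng.integers(0, 2, size=n)
        if min(np.sum(labels == 0), np.sum(labels == 1)) >= min_per_class:
            break
    return make_dataset(values, labels)


# ---------------------------------------------------------------- oracle --

def brute_rank_list(values, i):
    """Neighbor ordering of i by (distance, index) tuple sort."""
    n = len(values)
    entries = []
    for j in range(n):
        if j == i:
            continue
        d = math.sqrt(sum((a - b) ** 2 for a, b in zip(values[i], values[j])))
        entries.append((d, j))
    entries.sort()
    return entries


def brute_first_neighbors(values, labels, i):
    """(d_x, x, d_y, y): nearest same- and different-class neighbors of i."""
    d_x = d_y = None
    x = y = None
    for d, j in brute_rank_list(values, i):
        if labels[j] == labels[i]:
            if d_x is None:
                d_x, x = d, j
        elif d_y is None:
            d_y, y = d, j
        if d_x is not None and d_y is not None:
            return d_x, x, d_y, y
    raise AssertionError("class with < 2 members in oracle input")


def brute_profile(values, labels, i, tn):
    """(cn, cn_x, cn_y) under the shortest-prefix rule, by explicit scan."""
    same = diff = 0
    for pos, (_, j) in enumerate(brute_rank_list(values, i), start=1):
        if labels[j] == labels[i]:
            same += 1
        else:
            diff += 1
        if same >= tn and diff >= tn:
            return pos, same, diff
    raise AssertionError("TN infeasible in oracle input")


def brute_rivality(values, labels, i, tn):
    """Plain (tn=0) or weighted rivality by direct formula evaluation."""
    d_x, _, d_y, _ = brute_first_neighbors(values, labels, i)
    if tn == 0:
        a, b = d_x, d_y
    else:
        cn, cn_x, cn_y = brute_profile(values, labels, i, tn)
        a = d_x * (cn - cn_x) / cn
        b = d_y * (cn - cn_y) / cn
    if a == b:
        return -1e-6 if a == 0.0 else 0.0
    return (a - b) / (a + b)


def brute_diffclass_count(values, labels, i, tn_low, tn_high):
    """Different-class count within a same-class ordinal window."""
    ranked = brute_rank_list(values, i)
    same_seen = 0
    positions = {}
    for pos, (_, j) in enumerate(ranked, start=1):
        if labels[j] == labels[i]:
            same_seen += 1
            positions[same_seen] = pos
    start = 0 if tn_low == 1 else positions[tn_low - 1]
    end = positions[tn_high]
    return sum(
        1
        for pos, (_, j) in enumerate(ranked, start=1)
        if start < pos < end and labels[j] != labels[i]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_dataset():
    """Two tight 1-D clusters: trivially separable, no cliffs, no borders."""
    vals = np.array([0.0, 0.02, 0.04, 0.06, 0.94, 0.96, 0.98, 1.0])
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    return make_dataset(vals, labels)
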