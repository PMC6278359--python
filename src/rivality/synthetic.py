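"""Synthetic descriptor datasets with known ground truth.

Real QSAR descriptor tables never come with labels for which molecules are
activity cliffs; these generators plant that structure explicitly so every
diagnostic in the package can be tested against a known answer:

* two isotropic Gaussian clusters in descriptor space, one per class, with
  controllable centroid separation (in units of the within-cluster spread);
* *planted cliffs* — molecules labeled with one class but positioned inside
  the territory of the other.  They sit on the opposite cluster's
  periphery, at a fixed radius along angularly spread directions, so that
  (i) each cliff's nearest neighbor is an opposite-class cluster molecule,
  and (ii) no genuine cluster molecule acquires a cliff as *its* nearest
  neighbor — placing cliffs as i.i.d. draws from the opposite Gaussian
  would violate (ii) and silently corrupt the ground truth;
* *planted borders* — molecules at the midpoint between the centroids
  (plus isotropic jitter of at most 0.1 x the cluster spread), equidistant
  from both classes.

The generated matrix goes through the same clean -> range-scale pipeline
as real data, so downstream code sees exactly the production input format.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import DescriptorDataset, clean_columns, range_scale

__all__ = ["SyntheticSpec", "generate", "modelability_regimes"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic two-class descriptor dataset.

    Parameters
    ----------
    n_per_class : int
        Genuine cluster molecules per class (planted cliffs come on top).
    dim : int
        Descriptor dimensionality.
    separation : float
        Distance between the class centroids, in units of the within-cluster
        spread (the RMS distance from centroid, ``noise_sd * sqrt(dim)``).
    n_cliffs_per_class : int
        Molecules of each class planted inside the other class's territory.
    n_borders : int
        Molecules planted at the midpoint, labels alternating between classes.
    noise_sd : float
        Isotropic within-cluster standard deviation.
    seed : int
        RNG seed; identical spec + seed reproduces the dataset bit for bit.
    """

    n_per_class: int = 62
    dim: int = 10
    separation: float = 10.0
    n_cliffs_per_class: int = 0
    n_borders: int = 0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 2:
            raise ValueError("need at least 2 genuine molecules per class")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.n_cliffs_per_class < 0 or self.n_borders < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _spread_directions(rng, n: int, dim: int, max_cos: float = 0.25) -> np.ndarray:
    """Random unit vectors with pairwise cosine <= max_cos (rejection)."""
    dirs: list[np.ndarray] = []
    tries = 0
    while len(dirs) < n:
        v = rng.standard_normal(dim)
        v /= np.linalg.norm(v)
        if all(abs(float(v @ u)) <= max_cos for u in dirs):
            dirs.append(v)
        tries += 1
        if tries > 1000 * n:
            raise ValueError(
                f"cannot place {n} cliff directions in {dim} dimensions; lower "
                "n_cliffs_per_class or raise dim"
            )
    return np.array(dirs)


def generate(spec: SyntheticSpec):
    """Generate a dataset from a spec.

    Returns ``(dataset, truth)`` where ``dataset`` is cleaned and
    range-scaled and ``truth`` records the planted ``cliff_ids`` and
    ``border_ids`` plus the spec itself.
    """
    rng = np.random.default_rng(spec.seed)
    sd = spec.noise_sd
    # within-cluster spread = RMS distance from centroid = sd * sqrt(dim);
    # the separation parameter counts centroid distance in those units, so
    # "well separated" keeps meaning well separated as dim grows
    spread = sd * np.sqrt(spec.dim)
    centroids = {
        0: np.zeros(spec.dim),
        1: np.concatenate([[spec.separation * spread], np.zeros(spec.dim - 1)]),
    }
    rows, labels, ids = [], [], []

    for cls in (0, 1):
        pts = centroids[cls] + sd * rng.standard_normal((spec.n_per_class, spec.dim))
        for k, p in enumerate(pts):
            rows.append(p)
            labels.append(cls)
            ids.append(f"c{cls}_{k:03d}")

    # cliffs: class `cls` molecules on the rim of the *other* cluster, far
    # enough out that no genuine molecule adopts them as nearest neighbor,
    # close enough that their own nearest neighbor is opposite-class
    # rim radius: beyond the cluster's extreme points (~ sd*sqrt(2 ln n) along
    # any direction) by a margin larger than typical nearest-neighbor spacing
    cliff_ids = []
    radius = sd * (np.sqrt(2.0 * np.log(spec.n_per_class)) + 2.0 * np.sqrt(spec.dim))
    for cls in (0, 1):
        if spec.n_cliffs_per_class == 0:
            continue
        # directions orthogonal to the separation axis, so the planted rim
        # never stretches that axis's range and distort the class geometry
        sub = _spread_directions(rng, spec.n_cliffs_per_class, spec.dim - 1)
        dirs = np.hstack([np.zeros((len(sub), 1)), sub])
        other = centroids[1 - cls]
        for k, u in enumerate(dirs):
            mid = f"cliff{cls}_{k:02d}"
            rows.append(other + radius * u)
            labels.append(cls)
            ids.append(mid)
            cliff_ids.append(mid)

    border_ids = []
    midpoint = (centroids[0] + centroids[1]) / 2.0
    for k in range(spec.n_borders):
        jitter = rng.standard_normal(spec.dim)
        jitter *= (0.1 * sd * rng.uniform()) / np.linalg.norm(jitter)
        mid = f"border_{k:02d}"
        rows.append(midpoint + jitter)
        labels.append(k % 2)
        ids.append(mid)
        border_ids.append(mid)

    ds = DescriptorDataset(
        molecule_ids=tuple(ids),
        labels=np.array(labels),
        features=pd.DataFrame(
            np.array(rows), columns=[f"d{j:03d}" for j in range(spec.dim)]
        ),
    )
    ds = range_scale(clean_columns(ds))
    truth = {
        "cliff_ids": cliff_ids,
        "border_ids": border_ids,
        "spec": asdict(spec),
        "seed": spec.seed,
    }
    return ds, truth


def modelability_regimes(seed: int = 0):
    """Two contrasting fixtures: highly vs poorly modelable.

    The *high* fixture (62 + 62 genuine molecules, strong separation, three
    planted cliffs per class) mimics a dataset whose classes are compact
    and well separated except for a handful of cliffs; the *low* fixture
    (61 + 61, heavily overlapping clusters) mimics one where nearest-
    neighbor class membership is barely informative.

    Returns ``{"high": (dataset, truth), "low": (dataset, truth)}``.
    """
    high = generate(
        SyntheticSpec(
            n_per_class=59, dim=10, separation=10.0, n_cliffs_per_class=3,
            noise_sd=1.0, seed=seed,
        )
    )
    low = generate(
        SyntheticSpec(
            n_per_class=61, dim=10, separation=0.4, n_cliffs_per_class=0,
            noise_sd=1.0, seed=seed + 1,
        )
    )
    return {"high": high, "low": low}
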