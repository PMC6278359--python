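# Methods

## The model-free diagnosis

Every similarity-based classifier rests on the assumption that similar
molecules share activity. The rivality index turns that assumption into a
per-molecule statistic: with `d_x` the Euclidean distance (on the
range-scaled descriptor matrix) to the nearest same-class molecule and
`d_y` the nearest different-class distance,

    RI = (d_x − d_y) / (d_x + d_y) ∈ [−1, +1].

The sign of RI is the sign of `d_x − d_y`, so `RI > 0` identifies
molecules whose most similar neighbor carries the opposite label —
activity cliffs, the molecules any nearest-neighbor-like decision rule
must get wrong. Two degenerate cases are resolved explicitly: an exact
tie `d_x = d_y ≠ 0` yields `RI = 0` (a genuine border), while
`d_x = d_y = 0` (three or more coincident molecules across both classes)
is a 0/0 indetermination assigned the sentinel `−10⁻⁶`. The sentinel is
negative so CMODI still counts the molecule as classifiable, but it is
excluded from the border report and carries a flag, keeping it
distinguishable from a true zero.

The weighted variant replaces `d_x, d_y` with `d_x·w_x, d_y·w_y`, where
the weights come from the class composition of the molecule's
neighborhood. The neighborhood is defined by a threshold of neighbors
(TN): the shortest prefix of the molecule's ascending-distance neighbor
list containing at least TN molecules of each class. With prefix length
CN and per-class counts CN_x + CN_y = CN,

    w_x = (CN − CN_x)/CN,  w_y = (CN − CN_y)/CN,  w_x + w_y = 1.

A molecule swamped by opposite-class neighbors gets CN_x small, hence w_x
large, pushing RI positive even when `d_x` is marginally the smaller
distance. When CN_x = CN_y the weights cancel and the weighted index
equals the plain one exactly. The same tie/0-0 special cases apply to the
weighted numerator terms; although originally stated only for the plain
index, the identical indetermination arises, so the semantics are kept
consistent.

The prefix rule itself deserves a note: the neighborhood cardinality is
defined here operationally as the *shortest* prefix satisfying the TN
requirement for every class. This is the minimal reading of "minimum
number of neighbors of each class that must exist in the neighborhood"
and makes CN molecule-dependent, as intended.

CMODI (dataset modelability) is the unweighted mean over classes of the
fraction of molecules with `RI ≤ 0`. Two literal choices follow the
defining expression: `RI = 0` counts as classifiable (but is still
reported as a border), and classes contribute equally regardless of size
(for binary balanced data the distinction is moot; for imbalanced data
CMODI is a balanced, not a pooled, rate). With the plain index, CMODI is
provably the balanced accuracy of a leave-one-out 1-nearest-neighbor
classifier under the same tie-breaking — the test suite asserts this
equivalence exactly against an independent 1-NN implementation.

## Preprocessing

Columns containing any NaN/±Inf are dropped, as are all-zero columns.
Constant non-zero columns are also dropped: Max/Min scaling would be 0/0
for them and they carry no discriminative information (this third rule is
a package choice for the undefined case, logged per column). Remaining
columns are range-scaled to [0, 1] via `(x − min)/(max − min)`, and the
per-column `(min, max)` is retained.

External molecules are scaled with the *training* parameters by default,
so a test molecule outside the training descriptor box shows values
outside [0, 1] and an out-of-range flag — clean AD semantics with no test
information leaking into the scaling. Scaling the pooled matrix before
partitioning ("joint" mode) reproduces the historical protocol and can be
arranged by scaling before splitting (the `ad` CLI command does exactly
that, since it splits an already-scaled table); the default library path
is the leak-free one.

## Distances and determinism

Distances are plain Euclidean on the scaled matrix, double precision,
with the diagonal set to +Inf so a molecule never neighbors itself.
Neighbor lists are sorted ascending with ties broken by ascending
original row index; the sort is stable, so every derived quantity is
deterministic across platforms. Tie detection uses exact float equality —
on scaled data exact ties essentially only arise from duplicated rows,
and an epsilon would blur the sentinel semantics. Rank positions are
1-based everywhere ("first nearest neighbor" = position 1).

The in-set and external code paths compute distances with the identical
floating-point expression (row-wise sqrt of summed squared differences),
which makes the consistency property exact rather than approximate: the
external RI of a held-out training molecule is bit-equal to its in-set
value. Datasets of interest are at most a few thousand molecules, so the
exact O(n²) computation is used throughout; no approximate
nearest-neighbor indexing.

## Applicability domain and curation

External assessment adds test molecules one at a time to the training
context: distances run from the test molecule to training molecules only,
so a molecule's verdict is invariant to the composition of the rest of
the test set (asserted in tests). The verdict is a pure function of RI
and the border threshold: `outside` iff `RI > 0`, `border` iff
`|RI| ≤ threshold`, else `inside`. Computing RI requires the external
molecule's class label (`d_x` needs one), so AD assessment here is
label-aware — appropriate for external *validation*; an unlabeled-molecule
AD score would need a different statistic and is out of scope.

The default border threshold is the standard deviation of all pairwise
scaled distances. RI is dimensionless while that quantity is a distance,
so the default is a heuristic carried over from the method's convention;
it is exposed as a parameter everywhere and reported in every output.

Cliff erasure removes exactly the `RI > 0` molecules at a stated TN and
refuses to leave any class with fewer than two members. Survivors'
neighborhoods change, so the distance model is rebuilt afterwards;
iterating erase-then-recompute reaches a cliff-free fixed point quickly
on well-separated data.

Splits are stratified by class (both classes must appear on both sides
for the statistics to exist), with `round(fraction · class_size)`
training molecules per class, at least one per class on each side, and a
seeded generator for reproducibility.

## Benchmark harness

The comparison classifiers are scikit-learn's `RandomForestClassifier`
and `SVC(kernel="linear")` with library defaults, evaluated by
leave-one-out, repeated stratified 5-fold cross-validation (5 repeats by
default), or a single external validation. Defaults are deliberate: the
diagnosis claims to predict what an *untuned* similarity-respecting
learner will do. Statistics follow the binary-QSAR convention — SE is the
recall of the designated sensitivity class (first label in sorted order
by default), SP the other class's recall, ACC the pooled fraction
correct, CCR the balanced accuracy `(SE + SP)/2`. A single-class
evaluation set leaves SE or SP undefined; it is reported as NaN rather
than silently dropped. Outlier sets (misclassified molecules) are
cross-tabulated against cliff sets with a Jaccard score, with discordant
molecules annotated by border status — agreement is *reported*, not
asserted, since borders legitimately flip between runs.

## Synthetic data: what it emulates and what it does not

The generator produces two isotropic Gaussian clusters in descriptor
space, one per class, plus optional planted structure. Parameters and
defaults:

| parameter | default | meaning |
|---|---|---|
| `n_per_class` | 62 | genuine molecules per class (the canonical benchmark size) |
| `dim` | 10 | descriptor dimensionality after cleaning |
| `separation` | 10 | centroid distance in units of the within-cluster spread `noise_sd·√dim` |
| `n_cliffs_per_class` | 0 | molecules planted in the other class's territory |
| `n_borders` | 0 | molecules at the inter-centroid midpoint (jitter ≤ 0.1·noise_sd) |
| `noise_sd` | 1.0 | per-axis within-cluster standard deviation |

Separation is measured against the cluster's RMS radius rather than the
per-axis deviation because nearest-neighbor spacing grows like `√dim`:
a gap that looks enormous per-axis stops separating anything by dim ≈ 10.
With the default separation of 10 spreads, nearest neighbors are
same-class with overwhelming margin; separation 0 makes the two classes
identically distributed and the nearest-neighbor class a coin flip
(CMODI ≈ 0.5).

Planted cliffs are *not* i.i.d. draws from the opposite cluster's
Gaussian: an i.i.d. draw lands between genuine molecules and becomes some
genuine molecule's nearest neighbor, silently turning that molecule into
an unplanned cliff. Instead cliffs sit on the opposite cluster's rim — at
radius `noise_sd·(√(2·ln n) + 2√dim)` (beyond the cluster's extreme
points by more than the typical neighbor spacing) along directions that
are angularly spread (pairwise |cos| ≤ 0.25) and orthogonal to the
separation axis (so the planted rim never stretches that axis's range
under Max/Min scaling). This construction makes the planted set exactly
the `RI > 0` set at TN = 1 in the strong-separation regime, verified over
seed sweeps. Planted borders are placed at the midpoint with tiny
isotropic jitter; a single border is near-equidistant from both clusters,
but multiple borders become each other's nearest neighbors, so border
recovery is reported rather than asserted.

The fixture pair `modelability_regimes` mirrors the canonical
high/low-modelability contrast: a 124-molecule set (59 + 3 planted cliffs
per class, separation 10) whose CMODI ≈ 0.95 across TN 1–5, and a
122-molecule set (61 + 61, separation 0.4 — heavily overlapped) whose
CMODI stays below 0.8.

What passing these tests shows: the indexes, detection rules, curation
and AD protocol behave exactly as specified on geometry with known ground
truth. What they do not show: behavior on real CDK descriptor tables,
whose columns are correlated, heavy-tailed and redundant rather than
isotropic Gaussian. The indexes depend only on the distance matrix, so
the geometry is the right level of abstraction for correctness tests, but
empirical modelability values on real data are dataset properties, not
package properties. The optional `reproduce` command exists for that
comparison when the reference descriptor tables are available locally.

## Problem sizes and numerical choices

The bundled tests and the acceptance script run on generated data at the
benchmark scale (~120–130 molecules, 10 descriptors) or smaller random
instances (n ≤ 30, dim ≤ 5) where brute-force re-derivation is feasible;
oracle comparisons use 1e−12 absolute tolerance for floats and exactness
for integers. Seeds are explicit everywhere; identical spec + seed
reproduces datasets bit for bit.

## Known limitations

- AD assessment requires the external molecule's label; no unlabeled AD
  score is provided.
- The border threshold default mixes units (dimensionless RI vs a
  distance sd); treat it as a tunable heuristic.
- Multi-class inputs are accepted ("different class" aggregates all other
  classes; CMODI averages over k classes) but the binary path is the
  validated one.
- No regression (continuous-activity) extension.
- Benchmark numbers from other software stacks with different default
  hyperparameters will differ; the harness targets qualitative agreement
  of outlier sets, not cross-stack numeric parity.
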