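# rivality

Pre-modeling diagnostics for QSAR classification datasets: per-molecule
**rivality indexes**, dataset **modelability** (CMODI), **activity-cliff**
and **activity-border** detection, cliff-erasure curation, and a
distance-based **applicability-domain** (AD) assessment of external
molecules — with a Random Forest / linear-SVM harness to compare the
forecasts against what real classifiers do.

## Who this is for

QSAR modelers who, *before* fitting any classifier, want to know:

- how well can this descriptor table be modeled at all?
- which molecules will any similarity-based model misclassify (activity
  cliffs), and which training molecules are responsible?
- is a new molecule inside the applicability domain of a model trained on
  this set?

All of this is answered from nearest-neighbor geometry alone — no model is
built for the diagnosis itself.

## The statistic

For molecule *i*, let *d<sub>ix</sub>* be the Euclidean distance (on the
range-scaled descriptor matrix) to its nearest neighbor of the **same**
class, and *d<sub>iy</sub>* the distance to its nearest neighbor of a
**different** class. The rivality index is

```
RI_i = (d_ix − d_iy) / (d_ix + d_iy)        RI ∈ [−1, +1]
```

- `RI < 0`: the molecule is embedded in its own class — classifiable.
- `RI > 0`: the molecule is closer to the other class — an **activity
  cliff**, and the expected misclassification of any similarity-based model.
- `|RI| ≈ 0`: an **activity border**; the outcome depends sensitively on
  the training-set composition.
- `d_ix = d_iy ≠ 0` gives exactly 0; the degenerate `d_ix = d_iy = 0` case
  is assigned the sentinel `−10⁻⁶`.

The **weighted** index re-weights both distances by the class composition
of the molecule's neighborhood. Given a threshold of neighbors *TN*, the
neighborhood of *i* is the shortest prefix of its ascending-distance
neighbor list containing at least *TN* molecules of each class; with
cardinality *CN* and same/different-class counts *CN<sub>x</sub>*,
*CN<sub>y</sub>*:

```
w_x = (CN − CN_x) / CN,   w_y = (CN − CN_y) / CN
RI_i = (d_ix·w_x − d_iy·w_y) / (d_ix·w_x + d_iy·w_y)
```

The modelability index is the unweighted mean over classes of the fraction
of molecules with `RI ≤ 0`:

```
CMODI = (1/k) Σ_j  [ (1/M_j) Σ_{i ∈ class j} 1{RI_i ≤ 0} ]
```

With the plain index, CMODI is *exactly* the balanced accuracy of a
leave-one-out 1-nearest-neighbor classifier on tie-free data — which is
why it forecasts the correct classification rate (CCR) of similarity-based
models without fitting one.

## Worked example

Generate a synthetic dataset of two well-separated classes (20 molecules
each) with two planted activity cliffs per class, then diagnose it:

```bash
rivality simulate --n-per-class 20 --dim 5 --cliffs-per-class 2 --seed 7 --outdir sim
rivality rivality sim/dataset.csv --tn 0,1,2,3 --outdir riv
```

prints

```
Rivality diagnostics
==================================================================
molecules: 44   descriptors: 5   classes: 2
border threshold: 0.3489 (sd of pairwise scaled distances)
------------------------------------------------------------------
   TN    CMODI     M[0]     M[1]  cliffs  borders
plain    0.909    0.909    0.909       4        4
    1    0.909    0.909    0.909       4        0
    2    0.909    0.909    0.909       4        0
    3    0.909    0.909    0.909       4        0
==================================================================
```

Reading it: 40 of 44 molecules have `RI ≤ 0` (per-class modelability
0.909 = 20/22, CMODI 0.909), and the four cliffs detected at every TN are
exactly the four planted ones — `riv/summary.json` lists them
(`cliff0_00`, `cliff0_01`, `cliff1_00`, `cliff1_01`). Erase them and the
dataset becomes perfectly modelable:

```python
from rivality import read_descriptor_table, clean_columns, range_scale
from rivality import RivalityModel, erase_cliffs

ds = range_scale(clean_columns(read_descriptor_table("sim/dataset.csv")))
curated, removed = erase_cliffs(ds, tn=1)
print(removed)                                        # the 4 planted cliffs
print(RivalityModel(curated).fit(tn_list=(1,)).cmodi_[1])   # 1.0
```

The same objects drive the external AD protocol (`rivality ad`): the
dataset is split 80/20 several times, each training set is diagnosed and
optionally curated, and each test molecule's RI is computed against the
training molecules only — `RI > 0` means the molecule is outside the AD
and will likely be mispredicted, which the bundled RF/SVM external
validations let you verify.

## Library surface

- `read_descriptor_table` / `clean_columns` / `range_scale` /
  `apply_scale` — CSV/TSV descriptor tables, column cleaning, [0, 1]
  Max/Min scaling (external molecules are scaled with training parameters).
- `RivalityModel(dataset).fit(tn_list=...)` → `RivalityResults` with
  `ri_`, `cmodi_`, `per_class_modelability_`, `cliffs(tn)`, `borders(tn)`,
  `summary()`.
- `ApplicabilityDomain(train).assess(test_features, test_labels)` →
  `ADReport` (per-molecule RI, inside/border/outside verdicts, aggregate
  statistics).
- `erase_cliffs`, `split_dataset` — curation and stratified splits.
- `evaluate_loo` / `evaluate_cv` / `evaluate_external`,
  `compare_outliers` — the RF / linear-SVM comparison harness.
- `SyntheticSpec` / `generate` / `modelability_regimes` — synthetic
  datasets with planted ground truth.

Supplied descriptor tables are consumed as-is; computing descriptors from
structures is out of scope. If you have the Chembench CDK descriptor
tables for the YES1/MRP4 benchmark sets, `rivality reproduce --yes1 ...
--mrp4 ...` re-analyzes them for side-by-side inspection (the command
skips cleanly when the files are absent).

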