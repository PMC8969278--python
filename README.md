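# gaitmat

Reconstruction of footfalls from raw instrumented-walkway sensor data,
extraction of spatiotemporal and geometric gait features, and machine-learning
classification of impaired versus unimpaired gait.

Clinical pressure-sensitive walkways (a 90 × 420 cm mat with sensors on a
1.27 cm grid) record every activated cell as a time/position/pressure sample.
Proprietary software usually collapses these thousands of raw samples into a
handful of summary variables. `gaitmat` works from the raw export instead: it
rebuilds each footprint, derives the standard gait parameters from first
principles, and adds geometric descriptors of the footprint and the base of
support that summary software discards. The target users are gait researchers
and biomechanists who want a transparent, testable path from raw sensor data
to a classifier — for example to separate people with multiple-sclerosis-type
gait impairment from healthy controls.

## What it computes

**Footfall reconstruction.** Per-cell pressure time series are reduced to the
timestamp of peak pressure. The points of one pass are partitioned into *k*
footfalls by K-means (with *k* and the initial centroids seeded by a gap scan
of the walking-axis projection), enclosed in the minimum-area rotated
rectangle, and sliced into heel/mid/fore thirds with sub-centroids
**c**ₕ, **c**ₘ, **c**f.

**Standard features** (per footfall *i*, heel centers **h**, first/last
contact times t⁰, t¹): step length |Δy(**h**ᵢ, **h**ᵢ₋₁)|, stride length
‖**h**ᵢ − **h**ᵢ₋₂‖, step/stride width and base width as point–line
distances, step time t⁰ᵢ − t⁰ᵢ₋₁, stride time t⁰ᵢ − t⁰ᵢ₋₂, stance time
t¹ᵢ − t⁰ᵢ, single/double support times, the derived velocities, and the
signed toe angle ∠(midline, line of progression).

**Geometric features.** Hull area *A*ₕ = area(conv(footprint points)); base-
of-support area *A*ᵦ = area(conv(footprintᵢ ∪ footprintᵢ₋₁)); line-of-
progression deviation angle against the mat axis; foot length/width/area; and
the toe angle split into magnitude |θ| plus a binary direction
**1**[θ ≥ 0].

**Classification pipeline.** Anthropometric features are divided by subject
height; training folds are SMOTE-balanced and z-scaled; features with
pairwise Pearson |r| ≥ 0.8 are pruned (keeping the higher ANOVA-F member);
the ANOVA-F ranking is cut at the subset size that maximizes grouped
cross-validated SVM accuracy; categorical features are then reintroduced.
Logistic regression, SVM and gradient-boosted trees (XGBoost) are
grid-searched and evaluated under grouped five-fold cross-validation — all
rows of one subject visit stay in the same fold — reporting pooled accuracy,
precision, recall, F1, ROC/AUROC and PR/AUPRC.

**Synthetic walkway.** Because raw clinical exports are rarely shareable, the
package bundles a parametric gait simulator that plans alternating footfalls
from class-conditional profiles (step geometry, cadence, contact durations,
foot shape, walking-direction drift), rasterizes them onto the sensor grid
with a heel-to-toe pressure rollover, and records per-footfall ground truth
for every feature. All tests and the acceptance script run on it.

## Worked example

```python
from gaitmat import (generate_cohort, reduce_to_peak, split_passes,
                     assemble_feature_rows, run_experiment)

cohort = generate_cohort(n_patients=6, n_controls=4, passes_per_subject=3, seed=1)
points = reduce_to_peak(cohort.events)
table = assemble_feature_rows(split_passes(points, cohort.metadata))
print(f"{len(table)} footfall rows from {len(cohort.metadata)} passes")

result = run_experiment(table, feature_sets=("standard", "augmented"),
                        algorithms=("svm",), seed=2,
                        outer_folds=3, inner_folds=2, smote_k=3)
for (fs, algo), rep in result["reports"].items():
    m = rep.metrics
    print(f"{fs:9s} {algo}: accuracy {m['accuracy']:.1f}%  recall {m['recall']:.1f}%  "
          f"AUROC {rep.auroc:.3f}")
print("accuracy gain from geometric features:",
      f"{result['deltas']['svm']['accuracy']:+.1f}%")
```

prints

```
175 footfall rows from 30 passes
standard  svm: accuracy 83.6%  recall 100.0%  AUROC 0.995
augmented svm: accuracy 92.7%  recall 100.0%  AUROC 1.000
accuracy gain from geometric features: +9.1%
```

The simulated patients walk with shorter, more variable steps, a wider base
and longer double support. The standard spatiotemporal set alone separates
the classes well (83.6 % of footfalls correctly classified, AUROC 0.995);
adding the geometric footprint features lifts pooled accuracy by 9.1
percentage points. Row counts shrink from footfalls to classified rows
because features that need a neighbouring footfall are undefined at pass
boundaries and such rows are dropped before modelling.

The same steps are available from the shell:

```bash
gaitmat simulate --n-patients 6 --n-controls 4 --passes 3 --seed 1 --out data/
gaitmat extract  --raw data/raw_export.csv --meta data/metadata.csv --out features.csv
gaitmat classify --features features.csv --seed 2 --out report/
```

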