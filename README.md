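# arteryatlas

Probabilistic atlas construction and automatic labeling for the major
cerebral arteries, exercised end-to-end on synthetic vascular phantoms with
known ground truth.

## The problem

Angiographic MRI (e.g. the angiographic image reconstructed from 4D flow
acquisitions) shows the cerebral arteries as bright tubes, but turning such
volumes into per-artery measurements requires knowing *which* artery each
voxel belongs to. A probabilistic artery atlas answers this: for each named
artery `a` (internal carotid, basilar, vertebral, cerebral and communicating
arteries), a template-space map

```
p_a(v) = (number of subjects whose artery a occupies voxel v) / N_a
```

where `N_a` counts only the subjects that *possess* the artery — posterior
communicating arteries, for instance, are absent in most people. The named
collection of these maps is the atlas. New subjects are then labeled
automatically (AAIM — atlas-based artery identification): the subject's
vessel tree is segmented (3-voxel box smoothing, threshold at 18 % of the
maximum intensity), thinned to a one-voxel skeleton, decomposed into
branches between junction points, and every branch is assigned the artery
whose probability map scores highest along it (mean sampled probability,
existence threshold τ = 0.1). Assigned branches are re-inflated into the
vessel mask (7-voxel kernel, nearest-label rule) to recover volumetric
labels.

Atlas quality is characterized per artery by:

* **concatenated volume** — cm³ of voxels occupied in any subject;
* **AVR** (arterial volume ratio) — concatenated volume / mean per-subject
  volume; 1.0 means perfect inter-subject alignment, larger is worse;
* **dominating volume** — % of a map's support where it strictly exceeds
  every other map;
* **maximum probability** — the map's peak value.

These quantify how much a non-linear spatial normalization improves
inter-subject arterial alignment over a rigid-body one, and labeling
quality is validated by leave-one-out: rebuild the atlas without one
subject, label that subject, and categorize each artery into one of six
outcomes (correctly identified existing/non-existing, mislabeled
existing/non-existing, not identified, too short) from which sensitivity,
specificity and accuracy follow.

Because no imaging cohort ships with this package, a synthetic-data module
generates multi-subject cohorts of tubular circle-of-Willis-like phantoms
with per-artery prevalence, smooth random non-linear warps plus rigid
jitter, realistic intensity falloff and noise — and exact ground-truth
labels and transforms, so every pipeline stage can be tested against truth.

## Worked example

```python
import arteryatlas as aa
from arteryatlas.atlasbuild import metrics_table, whole_atlas_avr
from arteryatlas.phantom import default_criteria
from arteryatlas.validate import leave_one_out

config = aa.CohortConfig(n_subjects=8, seed=7)          # 64³ grid, 0.7 mm
specs = aa.default_artery_specs(config)                 # 11 arteries
cohort = aa.generate_cohort(specs, config)
processed = [aa.process_subject(s) for s in cohort]     # segment + skeletonize
atlas, rows = aa.build_cohort_atlas(processed, mode="nonlinear")
print(metrics_table(rows).round(2).to_string(index=False))
print(f"whole-atlas AVR: {whole_atlas_avr(rows):.2f}")
_, summary = leave_one_out(processed, criteria=default_criteria())
print(f"mean accuracy: {summary.attrs['mean_accuracy']:.1f} %")
```

prints

```
artery_name  n_included  mean_subject_volume_cm3  concatenated_volume_cm3  avr  dominating_volume_pct  max_probability
      ICA_R           8                     0.18                     0.26 1.42                  93.68              1.0
      ICA_L           8                     0.17                     0.26 1.50                  91.33              1.0
         BA           8                     0.10                     0.14 1.41                  93.75              1.0
      PCA_R           8                     0.04                     0.08 1.92                  86.64              1.0
      PCA_L           8                     0.05                     0.08 1.75                  93.44              1.0
      MCA_R           8                     0.04                     0.07 1.69                  93.52              1.0
      MCA_L           8                     0.05                     0.08 1.77                  83.20              1.0
      ACA_R           8                     0.03                     0.04 1.75                  81.68              1.0
      ACA_L           8                     0.03                     0.05 1.89                  84.78              1.0
     PCoA_R           3                     0.05                     0.08 1.70                  79.35              1.0
     PCoA_L           5                     0.06                     0.10 1.73                  79.38              1.0
whole-atlas AVR: 1.58
mean accuracy: 97.8 %
```

Reading the output: all eight subjects possess every trunk artery, while
the posterior communicating arteries appear in only 3 and 5 subjects
(prevalence 0.38). AVRs of 1.4–1.9 mean each probability map occupies
1.4–1.9× the volume of a single subject's artery — the residual spread
left by resampling under the known warps. Every artery dominates ~80–94 %
of its own territory, every map has a voxel where all included subjects
overlap (max probability 1.0), and leave-one-out labeling identifies
nearly every artery correctly.

A CLI mirrors the library: `arteryatlas simulate | skeletonize |
build-atlas | label | loo | stats` (see `arteryatlas --help`).

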