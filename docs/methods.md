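# Methods

This note documents the models, algorithms and numerical choices behind
`arteryatlas`, and what the synthetic phantoms do and do not establish.

## Coordinate conventions and transforms

Volumes are 3D grids with 0-based voxel indices; a 4×4 NIfTI-style affine
maps indices to world millimetres. Subject and template volumes share one
grid; "template space" is whatever grid the cohort defines (it plays the
role MNI space plays in a real study — no standard template is shipped).

A `SubjectTransform` stores the template→subject point map
`m(x) = A x + u(x)`, with `A` an invertible affine and `u` a millimetre
displacement field sampled on the template grid (trilinear interpolation
between nodes, nearest-edge extension outside). Design consequences:

* **Forward application** (normalizing a subject volume onto the template
  grid) samples the subject volume at `m(x)` for each template voxel —
  analytic and exact. This is the direction atlas construction uses.
* **Inverse application** (template→subject, used by the generator and for
  mapping subject skeleton points into atlas space) inverts `A` exactly and
  the displacement by fixed-point iteration `y ← A⁻¹(p − u(y))`, 10
  iterations. Free-form warps have no closed-form inverse; the iteration
  converges whenever `‖∇u‖ < 1`, comfortably true for the smooth,
  small-amplitude fields generated here (2 mm amplitude, 6 mm smoothness).
* `rigid_only` reduces `A` to its nearest rotation+translation via polar
  decomposition of the 3×3 block (scale/shear discarded, translation kept)
  and drops `u`. Non-linear registration is *not* re-estimated anywhere:
  "non-linear normalization" means applying the known generating warp, and
  "rigid-body" its rigid reduction, which preserves the comparison design
  (what does the deformable component buy?) in a self-contained package.

Intensities are resampled trilinearly, labels and masks nearest-neighbour
(labels must stay integral). Smoothing uses a width-3 box filter with
zero-padding at borders (vessels are interior; the fixed rule keeps results
bit-reproducible). Thresholding is inclusive (`≥ fraction · max`) at 18 %
of the maximum of the smoothed image — smoothing precedes binarization, so
the threshold refers to the smoothed maximum.

## Skeletonization

`thin` is a sequential simple-point thinning: six directional subiterations
(up/down/north/south/east/west) peel border voxels in lexicographic order;
a voxel is deleted only if it is a *simple point* — its punctured
26-neighbourhood has exactly one 26-connected object component and its
18-neighbourhood has exactly one 6-connected background component adjacent
to it (the Malandain–Bertrand characterization) — and not a curve endpoint
(≤ 1 remaining neighbour). Sequential deletion with re-checking makes
topology preservation unconditional: components and tunnels are invariants,
verified by property tests (blob component counts, a torus thins to a
single cycle, a one-voxel line is a fixed point, no 2×2×2 block survives).
Simplicity tests are memoized on the 27-bit neighbourhood pattern, which
makes the procedure fast in practice because vascular masks contain few
distinct local configurations. The cost of endpoint protection is that tube
ends retreat by roughly one tube radius before a protected endpoint forms;
branch-length margins below account for this.

`build_graph` classifies skeleton voxels with ≥ 3 neighbours (26-connected)
as junction voxels, merges mutually adjacent junction voxels into clusters
(a thick T-joint yields one junction, and in 26-connectivity the first
voxel of a perpendicular spur is itself junction-adjacent and fuses into
the cluster), and decomposes the remaining degree-≤ 2 voxels into ordered
branch paths. Branch ids are assigned in lexicographic order of each
branch's smallest endpoint, so the decomposition is deterministic.

`prune` alternates until stable: (a) terminal branches shorter than 8
voxels are deleted iteratively; (b) graph cycles are broken by deleting the
shortest participating branch (ties to the lower id) — except that an
isolated closed ring is *opened* by removing a single voxel rather than
discarded whole. After every deletion the voxel set is re-thinned (a clean
path is a fixed point of thinning, so this only strips junction voxels made
redundant by the deletion) and the graph recomputed. Pruning that would
empty the skeleton raises instead of returning an empty object.

## Atlas construction

Labeled skeleton voxels are re-inflated into the binary vessel tree by
constrained dilation: each label propagates within a 7×7×7 cube (the
literal reading of "kernel of size seven voxels"; reach 3), clipped to the
mask; voxels reached by several labels take the Euclidean-nearest labeled
skeleton voxel, ties to the lower artery id (per-label distance transforms
stacked in id order make this deterministic). Re-inflation never labels
outside the mask.

Probability maps divide per-voxel occupancy counts by the number of
*included* arteries, not the cohort size — a subject without the artery
does not dilute its map. Characterization metrics follow the definitions in
the README; two numerical points matter:

* AVR denominators are averaged as integer voxel counts and converted to
  cm³ once, so a cohort of voxel-identical arteries yields AVR exactly 1.0
  rather than 1.0 ± 1 ulp.
* Dominating volume uses strict inequality: exact ties do not dominate.
* The whole-atlas AVR aggregates as Σ concatenated volumes / Σ mean
  volumes; this aggregation reproduces both published whole-atlas values
  from the published per-artery columns, which is why it was adopted.

The rigid-body comparison atlas resamples each artery's binary mask
linearly under the rigid-only transform and re-binarizes at the threshold
that conserves the artery's native voxel count (keeping all tied voxels;
if fewer positive voxels exist than the target, all are kept and a warning
raised). The conservation target is the per-subject, per-artery native
volume — the alternative reading (conserving each final map's concatenated
volume) was rejected as it would make per-subject volumes, and hence AVR
denominators, depend on the atlas being built.

## Automatic labeling (AAIM)

Branch scoring samples each artery's probability map (trilinear) at the
branch's voxels mapped to template space; the score is the mean, with the
sum kept only for tie-breaking. A branch is assigned its argmax artery if
the mean score reaches τ = 0.1, ties broken by higher summed probability
then lexicographic name; an artery is "found" iff it owns ≥ 1 branch.
Scoring rule and τ are parameters because the branch-scoring details admit
reasonable variants; assignment is branch-level because skeleton branches
are the natural labeling unit. The pipeline is deterministic, and raising τ
can only shrink the set of found arteries (tested).

## Validation

The reference ("manual") labeling of a synthetic subject is produced on the
same segmented tree the automatic labeling sees: each skeleton voxel takes
the ground-truth label at its position, falling back to the nearest labeled
truth voxel within 2.5 voxels (the segmented tube is slightly wider than
the true lumen). Labeling is per voxel, not per branch: when a side branch
is absent the artery border falls *inside* a through-running branch,
mirroring how manual labeling places borders by morphology when no junction
exists. An artery must keep ≥ 3 skeleton voxels to count as present in the
reference. This construction makes the evaluation measure branch-assignment
correctness rather than segmentation width.

Outcome categories follow fixed quantitative surrogates for what a human
rater judges case-by-case: "correct vs mislabeled" uses a purity threshold
(≥ 90 % of auto-labeled voxels inside the reference artery; configurable),
and "too short" uses per-artery segment criteria — a connected centerline
run of a minimum physical length, measured as the weighted diameter of the
26-adjacency graph (diagonal steps scaled) plus one voxel extent, so a
straight run of n voxels measures n·voxel_size. Confusion metrics round
half-up to integer percent; specificity is undefined without any TN or FP;
the summary accuracy is the unweighted mean of per-artery accuracies.

Leave-one-out rebuilds each held-out subject's atlas by subtracting its
contribution from precomputed occupancy sums (exactly equivalent to
rebuilding from scratch, and linear instead of quadratic in cohort size).

`wilcoxon_signed_rank` drops zero differences, average-ranks ties, and for
n ≤ 25 enumerates the exact null distribution of W⁺ by subset-sum
convolution over doubled ranks (integers even with ties); beyond that a
normal approximation with tie correction applies. `spearman_rho` is the
Pearson correlation of average-ranked values. Both are cross-checked
against independent oracles (exhaustive 2ⁿ enumeration, scipy, the
closed-form tie-free formula) in the tests.

## The phantom generator

`generate_cohort` emulates the statistical structure the pipeline assumes:

* **Geometry** — 11 tubes arranged circle-of-Willis-like (bilateral
  ICA/MCA/ACA/PCA/PCoA + basilar), scaled to the grid extent. Segment
  lengths keep every anatomical junction at least 8+3 voxels from free
  ends so the pruning rule cannot dissolve junctions; tube separations
  exceed the sum of mask radii under the default warps. Radii 0.9–1.6 mm
  are free parameters (published per-artery volumes exist but radii and
  lengths do not, so no calibration to them is attempted).
* **Prevalence** — ICA/MCA/BA ≈ 1, PCA 0.98, ACA 0.94, PCoA 0.38,
  mirroring population frequencies; presence is sampled per subject.
* **Contrast** — flat tube core with a cosine rim falloff over one voxel,
  peak intensities 0.8–1.0 (PCoA 0.8, the faintest: slow flow), additive
  Gaussian noise (sd 0.02 of peak), clipped at zero. The profile is chosen
  so 18 %-of-max thresholding recovers the lumen to within a voxel — a
  stated contract of the generator, tested directly.
* **Deformation** — per-subject Gaussian-filtered white noise rescaled so
  the largest displacement is `deform_amplitude_mm` (default 2 mm,
  smoothness 6 mm), composed with a random rigid jitter (≤ 3°, ≤ 1.5 mm,
  about the grid centre). Intensities warp trilinearly, labels
  nearest-neighbour. All randomness flows from one seed through
  `SeedSequence.spawn`, so identical configs are bit-identical.

Default study conditions — 20 subjects on a 64³ grid at 0.7 mm — were
chosen as the smallest scale at which the 11-artery geometry is resolved
(a 48³ grid leaves the thin ACA under 3 skeleton voxels) while the full
two-atlas + leave-one-out experiment runs in about a minute.

**What passing phantoms does not show.** The phantoms have no intensity
inhomogeneity, no flow voids or gaps in low-flow arteries, no kissing
vessels, and topologically analogous rather than anatomically faithful
geometry; normalization uses the *known* generating warp rather than an
estimated registration, so the results bound what the pipeline does under
ideal normalization, not registration quality itself. The comparison
rigid-vs-non-linear is therefore structural (does removing the deformable
component degrade alignment?) rather than a registration benchmark.

## Known limitations

* Endpoint retreat during thinning shortens terminal branches by roughly a
  tube radius; criteria and phantom lengths include this margin, but very
  short stubby arteries (< ~8 voxels of centerline) are not representable.
* The approximate field inverse introduces sub-voxel error that double
  nearest-neighbour resampling (generation + normalization) turns into
  ±1-voxel label jitter; phantom AVRs under known-warp normalization are
  therefore ~1.4–2 rather than exactly 1.
* `reinflate`'s literal 7-voxel kernel cannot bridge label gaps wider than
  3 voxels; unreached mask voxels stay background by design.
* Specificity is undefined for arteries that are always present (no TN or
  FP can occur), as in any leave-one-out of near-universal structures.
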