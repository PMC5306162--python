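"""Cohort-level composition: from synthetic subjects to template-space artery
labels and atlases.

For each subject the angiographic image is segmented and skeletonized, and
the skeleton branches receive their *reference* artery labels from the
generator's ground truth (each branch takes the majority truth label along
its voxels — the stand-in for manual branch labeling, which in a real study
is performed on the same segmented tree).  The labeled branches are
re-inflated into the vessel mask and the resulting label volume is
normalized to template space, either

* ``nonlinear`` — through the subject's full known transform (labels
  nearest-neighbour), or
* ``rigid`` — through the rigid-only reduction, resampling each artery's
  mask linearly and re-binarizing at the volume-conserving threshold
  (each artery keeps its native voxel count up to ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .aaim import LabelingResult
from .atlasbuild import (
    Atlas,
    AtlasMetricsRow,
    build_atlas,
    reinflate,
    volume_conserving_binarize,
)
from .phantom import SyntheticSubject
from .skeleton import Skeleton, branch_labels_to_volume, skeletonize_mask
from .volumes import (
    BinaryVolume,
    LabelVolume,
    ScalarVolume,
    apply_transform,
    box_smooth,
    rigid_only,
    threshold_binarize,
)

__all__ = ["ProcessedSubject", "process_subject", "labels_to_template", "build_cohort_atlas"]


@dataclass
class ProcessedSubject:
    subject: SyntheticSubject
    mask: BinaryVolume
    skeleton: Skeleton
    branch_truth: dict[int, int]  # branch id -> artery id (0 = unlabeled)
    reference_labels: LabelVolume  # re-inflated truth labeling of the mask
    reference_presence: dict[str, bool]

    def reference_result(self) -> LabelingResult:
        """Reference labeling wrapped as a LabelingResult (for categorize)."""
        names = {i: n for i, n in sorted(self.reference_labels.name_table.items())}
        assignments: dict[str, list[int]] = {n: [] for n in names.values()}
        for bid, aid in self.branch_truth.items():
            if aid:
                assignments[names[aid]].append(bid)
        statuses = {n: ("found" if assignments[n] else "not_found") for n in names.values()}
        return LabelingResult(statuses, assignments, self.reference_labels, self.skeleton)


def process_subject(subject: SyntheticSubject, threshold_fraction: float = 0.18,
                    smooth_width: int = 3, min_branch_vox: int = 8,
                    reinflate_kernel: int = 7, label_reach_vox: float = 2.5,
                    min_presence_vox: int = 3) -> ProcessedSubject:
    """Segment, skeletonize, and truth-label one subject's vessel tree.

    Skeleton voxels take the ground-truth label at their position, falling
    back to the nearest labeled truth voxel within ``label_reach_vox`` (the
    segmented tube is slightly wider than the true lumen, so centerline ends
    can sit just outside it).  Labeling is per voxel, not per branch: when a
    side branch is absent the artery border falls inside a through-running
    branch, exactly as manual labeling places borders by morphology when no
    junction exists.  An artery is present in the reference iff it keeps at
    least ``min_presence_vox`` skeleton voxels.
    """
    mask = threshold_binarize(box_smooth(subject.angio, smooth_width), threshold_fraction)
    skel = skeletonize_mask(mask, min_branch_vox=min_branch_vox)

    truth = subject.truth_labels
    # nearest-truth lookup: EDT on the background of labeled truth voxels
    dist, (ix, iy, iz) = ndimage.distance_transform_edt(
        truth.labels == 0, return_indices=True
    )
    skel_labels = np.zeros(skel.shape, dtype=np.int32)
    for b in skel.branches:
        idx = tuple(np.array(b.path).T)
        direct = truth.labels[idx]
        near = truth.labels[ix[idx], iy[idx], iz[idx]]
        vals = np.where(direct > 0, direct, np.where(dist[idx] <= label_reach_vox, near, 0))
        skel_labels[idx] = vals

    counts = np.bincount(skel_labels.ravel(), minlength=max(truth.name_table) + 1)
    presence = {
        name: bool(counts[aid] >= min_presence_vox)
        for aid, name in truth.name_table.items()
    }
    for aid, name in truth.name_table.items():
        if not presence[name]:
            skel_labels[skel_labels == aid] = 0

    branch_truth: dict[int, int] = {}  # majority label per branch (diagnostic)
    for b in skel.branches:
        vals = skel_labels[tuple(np.array(b.path).T)]
        vals = vals[vals > 0]
        branch_truth[b.id] = (
            int(np.unique(vals, return_counts=True)[0][
                np.argmax(np.unique(vals, return_counts=True)[1])]) if vals.size else 0
        )

    skel_label_vol = LabelVolume(skel_labels, truth.name_table, mask.voxel_size_mm, mask.affine)
    reference = reinflate(skel_label_vol, mask, kernel_vox=reinflate_kernel)
    return ProcessedSubject(subject, mask, skel, branch_truth, reference, presence)


def labels_to_template(proc: ProcessedSubject, mode: str = "nonlinear") -> LabelVolume:
    """Normalize a subject's reference label volume to template space."""
    transform = proc.subject.transform
    ref = proc.reference_labels
    if mode == "nonlinear":
        return apply_transform(ref, transform, direction="forward", interp="nearest")
    if mode != "rigid":
        raise ValueError("mode must be 'nonlinear' or 'rigid'")

    rigid = rigid_only(transform)
    out = np.zeros(ref.shape, dtype=np.int32)
    best = np.full(ref.shape, -np.inf)
    for aid in sorted(proc.reference_labels.name_table):
        native = ref.labels == aid
        n_native = int(np.count_nonzero(native))
        if n_native == 0:
            continue
        floated = ScalarVolume(native.astype(float), ref.voxel_size_mm, ref.affine)
        resampled = apply_transform(floated, rigid, direction="forward", interp="linear")
        mask = volume_conserving_binarize(resampled, n_native)
        # lower id wins voxels claimed by two arteries after re-binarization
        take = mask.mask & (out == 0)
        out[take] = aid
        best[take] = resampled.values[take]
    return LabelVolume(out, ref.name_table, ref.voxel_size_mm, ref.affine)


def build_cohort_atlas(processed: list[ProcessedSubject], mode: str = "nonlinear",
                       space_tag: str | None = None) -> tuple[Atlas, list[AtlasMetricsRow]]:
    """Normalize every subject and build the atlas plus its metrics table.

    Mean subject volumes entering the AVR are the native-space (subject-grid)
    artery volumes, as in an angiographic study.
    """
    template_labels = [labels_to_template(p, mode=mode) for p in processed]
    name_table = processed[0].reference_labels.name_table
    native: dict[str, list[int]] = {}
    for aid, name in sorted(name_table.items()):
        counts = [
            int(np.count_nonzero(p.reference_labels.labels == aid)) for p in processed
        ]
        native[name] = [c for c in counts if c > 0]
    return build_atlas(
        template_labels,
        space_tag=space_tag or mode,
        subject_volume_counts=native,
    )
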