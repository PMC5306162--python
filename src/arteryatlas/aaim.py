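"""Atlas-based automatic artery identification (AAIM).

Given a subject's angiographic volume, a probability-map atlas, and the
subject's normalization transform, the skeleton of the segmented vessel tree
is decomposed into branches and each branch is scored against every artery's
probability map: the score is the mean map probability sampled (trilinearly)
at the branch voxels mapped into template space.  A branch is assigned to
the highest-scoring artery if that score reaches the existence threshold
``tau`` (default 0.1); an artery is *found* iff at least one branch is
assigned to it.  Assigned branches are re-inflated into the vessel mask to
produce the labeled volume.  The procedure is fully deterministic.

Scoring-rule knobs (mean vs summed score, ``tau``) are parameters, since
branch scoring admits reasonable variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlasbuild import Atlas, reinflate
from .skeleton import Skeleton, branch_labels_to_volume, skeletonize_mask
from .volumes import (
    BinaryVolume,
    LabelVolume,
    ScalarVolume,
    SubjectTransform,
    box_smooth,
    map_points_subject_to_template,
    threshold_binarize,
)

__all__ = ["ScoreTable", "LabelingResult", "score_branches", "assign_labels", "label_subject"]


@dataclass
class ScoreTable:
    """Per-(branch, artery) atlas probabilities: mean over branch voxels and
    the sum (used only to break argmax ties)."""

    mean: pd.DataFrame  # index: branch id, columns: artery names
    total: pd.DataFrame


@dataclass
class LabelingResult:
    statuses: dict[str, str]  # artery name -> 'found' | 'not_found'
    assignments: dict[str, list[int]]  # artery name -> branch ids
    label_volume: LabelVolume
    skeleton: Skeleton

    def artery_skeleton_voxels(self, name: str) -> list[tuple[int, int, int]]:
        ids = set(self.assignments.get(name, []))
        out = []
        for b in self.skeleton.branches:
            if b.id in ids:
                out.extend(b.path)
        return out


def score_branches(skel: Skeleton, atlas: Atlas, transform: SubjectTransform,
                   subject_affine: np.ndarray) -> ScoreTable:
    """Score every branch against every probability map.

    Branch voxels (subject grid indices) are mapped to template millimetre
    space through the inverse of the subject transform's template->subject
    point map, then each map is sampled with linear interpolation; voxels
    falling outside the atlas grid contribute zero.
    """
    names = atlas.names
    mean_rows, total_rows, index = [], [], []
    for b in skel.branches:
        pts_vox = np.asarray(b.path, dtype=float)
        pts_mm = pts_vox @ subject_affine[:3, :3].T + subject_affine[:3, 3]
        tpl_mm = map_points_subject_to_template(transform, pts_mm)
        means, totals = [], []
        for name in names:
            pmap = atlas.maps[name]
            vox = np.linalg.inv(pmap.affine)[:3, :3] @ tpl_mm.T + np.linalg.inv(
                pmap.affine
            )[:3, 3][:, None]
            vals = ndimage.map_coordinates(pmap.values, vox, order=1, mode="constant", cval=0.0)
            means.append(float(vals.mean()))
            totals.append(float(vals.sum()))
        index.append(b.id)
        mean_rows.append(means)
        total_rows.append(totals)
    mean_df = pd.DataFrame(mean_rows, index=index, columns=names)
    total_df = pd.DataFrame(total_rows, index=index, columns=names)
    return ScoreTable(mean=mean_df, total=total_df)


def assign_labels(table: ScoreTable, tau: float = 0.1) -> dict[int, str | None]:
    """Assign each branch the argmax-scoring artery if its mean score reaches
    ``tau``; ties broken by higher summed probability, then by artery name.

    Returns branch id -> artery name (or None for unlabeled branches).
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    out: dict[int, str | None] = {}
    for bid in table.mean.index:
        row = table.mean.loc[bid]
        best = row.max()
        if not np.isfinite(best) or best < tau:
            out[bid] = None
            continue
        tied = [n for n in table.mean.columns if row[n] == best]
        if len(tied) > 1:
            tot = table.total.loc[bid]
            best_tot = max(tot[n] for n in tied)
            tied = sorted(n for n in tied if tot[n] == best_tot)
        out[bid] = tied[0]
    return out


def label_subject(angio: ScalarVolume, atlas: Atlas, transform: SubjectTransform,
                  tau: float = 0.1, threshold_fraction: float = 0.18,
                  smooth_width: int = 3, min_branch_vox: int = 8,
                  reinflate_kernel: int = 7,
                  mask: BinaryVolume | None = None,
                  skeleton: Skeleton | None = None) -> LabelingResult:
    """Full labeling pipeline for one subject.

    Smooth -> threshold -> skeletonize/prune -> score -> assign -> re-inflate.
    ``mask`` / ``skeleton`` may be supplied to reuse precomputed stages (the
    leave-one-out harness does this); they must come from the same settings.
    """
    if mask is None:
        mask = threshold_binarize(box_smooth(angio, smooth_width), threshold_fraction)
    if skeleton is None:
        skeleton = skeletonize_mask(mask, min_branch_vox=min_branch_vox)

    table = score_branches(skeleton, atlas, transform, angio.affine)
    branch_to_artery = assign_labels(table, tau=tau)

    names = atlas.names
    name_to_id = {n: i + 1 for i, n in enumerate(names)}
    assignment_ids = {
        bid: name_to_id[a] for bid, a in branch_to_artery.items() if a is not None
    }
    name_table = {i + 1: n for i, n in enumerate(names)}
    branch_label_vol = branch_labels_to_volume(skeleton, assignment_ids, mask, name_table)
    labeled = reinflate(branch_label_vol, mask, kernel_vox=reinflate_kernel)

    assignments: dict[str, list[int]] = {n: [] for n in names}
    for bid, artery in branch_to_artery.items():
        if artery is not None:
            assignments[artery].append(bid)
    statuses = {n: ("found" if assignments[n] else "not_found") for n in names}
    return LabelingResult(
        statuses=statuses,
        assignments=assignments,
        label_volume=labeled,
        skeleton=skeleton,
    )
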