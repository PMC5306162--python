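"""Probability-map atlas construction and characterization.

Labeled skeleton branches are re-inflated into volumetric artery labels by
constrained dilation into the binary vessel tree; per-artery binary volumes
normalized to template space are averaged into probability maps (the voxel
value is the fraction of subjects *possessing the artery* whose artery
occupies the voxel); and the maps are characterized by the four alignment
measures used to compare normalization strategies:

* concatenated volume — physical volume of all non-zero voxels of a map;
* arterial volume ratio (AVR) — concatenated volume over the mean
  per-subject artery volume; 1.0 means perfect inter-subject alignment and
  larger values mean poorer alignment;
* dominating volume — percentage of a map's non-zero voxels where it is
  strictly greater than every other map in the atlas;
* maximum probability — the map's peak value (1.0 when every included
  subject overlaps in some voxel).

``volume_conserving_binarize`` supports the rigid-body comparison atlas:
after linear resampling under a rigid transform, each artery is re-binarized
at the threshold that conserves its native voxel count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import BinaryVolume, LabelVolume, ScalarVolume

__all__ = [
    "ProbabilityMap",
    "Atlas",
    "AtlasMetricsRow",
    "reinflate",
    "build_probability_map",
    "concatenated_volume",
    "arterial_volume_ratio",
    "dominating_volume",
    "max_probability",
    "whole_atlas_avr",
    "volume_conserving_binarize",
    "build_atlas",
    "metrics_table",
]


@dataclass
class ProbabilityMap:
    artery_name: str
    values: np.ndarray  # in [0, 1]; every value is k / n_included
    n_included: int
    voxel_size_mm: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0 or self.values.max() > 1 + 1e-9:
            raise ValueError("probability values must lie in [0, 1]")
        if self.n_included < 1:
            raise ValueError("n_included must be >= 1")
        self.voxel_size_mm = np.broadcast_to(
            np.asarray(self.voxel_size_mm, dtype=float), (3,)
        ).copy()
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class Atlas:
    """Named collection of probability maps on one common grid."""

    maps: dict[str, ProbabilityMap]
    space_tag: str = "template"

    def __post_init__(self):
        shapes = {m.values.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError("all probability maps must share one grid")

    @property
    def names(self) -> list[str]:
        return list(self.maps)


@dataclass
class AtlasMetricsRow:
    artery_name: str
    n_included: int
    mean_subject_volume_cm3: float
    concatenated_volume_cm3: float
    avr: float
    dominating_volume_pct: float
    max_probability: float


def reinflate(branch_labels: LabelVolume, mask: BinaryVolume, kernel_vox: int = 7) -> LabelVolume:
    """Re-inflate labeled skeleton voxels into the binary vessel tree.

    Each labeled skeleton voxel propagates its label within a cubic
    neighbourhood of ``kernel_vox`` voxels; the dilated labels are clipped to
    the mask.  A mask voxel reached by several labels takes the label of the
    Euclidean-nearest labeled skeleton voxel (ties to the lower id); mask
    voxels reached by no label stay background.
    """
    if kernel_vox < 1 or kernel_vox % 2 == 0:
        raise ValueError("kernel size must be an odd positive integer")
    if np.any((branch_labels.labels > 0) & ~mask.mask):
        raise ValueError("labeled skeleton voxels must lie inside the mask")
    reach = kernel_vox // 2
    cube = np.ones((kernel_vox,) * 3, dtype=bool)
    ids = [int(i) for i in np.unique(branch_labels.labels) if i != 0]
    out = np.zeros(branch_labels.shape, dtype=np.int32)
    if not ids:
        return LabelVolume(out, branch_labels.name_table,
                           branch_labels.voxel_size_mm, branch_labels.affine)

    best = np.full(branch_labels.shape, np.inf)
    for aid in ids:  # ascending id order; ties keep the earlier (lower) id
        seed = branch_labels.labels == aid
        reached = ndimage.binary_dilation(seed, structure=cube) & mask.mask
        dist = ndimage.distance_transform_edt(~seed)
        better = reached & (dist < best)
        out[better] = aid
        best[better] = dist[better]
    return LabelVolume(out, branch_labels.name_table,
                       branch_labels.voxel_size_mm, branch_labels.affine)


def build_probability_map(artery_name: str, label_volumes: Sequence[LabelVolume | BinaryVolume],
                          label_id: int | None = None) -> ProbabilityMap:
    """Average per-subject binary artery volumes into a probability map.

    The denominator is the number of *included* arteries — subjects in which
    the artery has at least one voxel — not the cohort size, so every value
    is k / n_included.
    """
    binaries = []
    meta = None
    for vol in label_volumes:
        if isinstance(vol, BinaryVolume):
            b = vol.mask
        else:
            if label_id is None:
                inv = {v: k for k, v in vol.name_table.items()}
                if artery_name not in inv:
                    b = np.zeros(vol.shape, dtype=bool)
                    binaries.append(b)
                    meta = meta or (vol.voxel_size_mm, vol.affine)
                    continue
                b = vol.labels == inv[artery_name]
            else:
                b = vol.labels == label_id
        binaries.append(b)
        meta = meta or (vol.voxel_size_mm, vol.affine)
    shapes = {b.shape for b in binaries}
    if len(shapes) != 1:
        raise ValueError("all volumes must share one grid")
    included = [b for b in binaries if b.any()]
    if not included:
        raise ValueError(f"artery '{artery_name}' is absent in every subject")
    values = np.sum(included, axis=0, dtype=float) / len(included)
    vox, affine = meta
    return ProbabilityMap(artery_name, values, len(included), vox, affine)


def concatenated_volume(pmap: ProbabilityMap) -> float:
    """Volume (cm^3) of voxels occupied by the artery in any subject."""
    return float(np.count_nonzero(pmap.values > 0) * pmap.voxel_volume_mm3 / 1000.0)


def arterial_volume_ratio(pmap: ProbabilityMap, subject_volumes_cm3: Sequence[float]) -> float:
    """AVR = concatenated volume / mean per-subject volume (included subjects
    only).  Equals 1.0 exactly when all subject volumes coincide voxel-wise."""
    vols = np.asarray(subject_volumes_cm3, dtype=float)
    if vols.size == 0:
        raise ValueError("AVR needs at least one subject volume")
    if np.any(vols <= 0):
        raise ValueError("subject volumes must be positive")
    return concatenated_volume(pmap) / float(vols.mean())


def dominating_volume(target: ProbabilityMap, atlas: Atlas) -> float:
    """Percent of the target's non-zero voxels where it strictly exceeds
    every other map (exact ties do not dominate)."""
    if target.artery_name not in atlas.maps:
        raise ValueError(f"{target.artery_name} not in atlas")
    support = target.values > 0
    n_support = int(np.count_nonzero(support))
    if n_support == 0:
        return 0.0
    others = [m.values for n, m in atlas.maps.items() if n != target.artery_name]
    if not others:
        return 100.0
    other_max = np.maximum.reduce(others)
    wins = support & (target.values > other_max)
    return 100.0 * int(np.count_nonzero(wins)) / n_support


def max_probability(pmap: ProbabilityMap) -> float:
    mx = float(pmap.values.max())
    if mx <= 0:
        raise ValueError("probability map is empty")
    return mx


def whole_atlas_avr(rows: Sequence[AtlasMetricsRow] | pd.DataFrame) -> float:
    """Atlas-level AVR: sum of concatenated volumes over the sum of mean
    per-subject volumes across arteries."""
    if isinstance(rows, pd.DataFrame):
        conc = rows["concatenated_volume_cm3"].to_numpy(dtype=float)
        mean = rows["mean_subject_volume_cm3"].to_numpy(dtype=float)
    else:
        rows = list(rows)
        conc = np.array([r.concatenated_volume_cm3 for r in rows], dtype=float)
        mean = np.array([r.mean_subject_volume_cm3 for r in rows], dtype=float)
    if conc.size == 0:
        raise ValueError("at least one metrics row required")
    return float(conc.sum() / mean.sum())


def volume_conserving_binarize(resampled: ScalarVolume | np.ndarray,
                               target_volume_vox: int) -> BinaryVolume | np.ndarray:
    """Re-binarize a linearly resampled artery at the threshold that keeps
    (at least) ``target_volume_vox`` voxels: the threshold is the target-th
    largest positive value and all tied voxels are kept.

    If the resampled volume has fewer positive voxels than the target, all
    positive voxels are returned and a warning is issued.
    """
    if target_volume_vox < 1:
        raise ValueError("target volume must be >= 1 voxel")
    arr = resampled.values if isinstance(resampled, ScalarVolume) else np.asarray(resampled, float)
    pos = arr[arr > 0]
    if pos.size < target_volume_vox:
        warnings.warn(
            "fewer positive voxels than the conservation target; keeping all",
            RuntimeWarning,
            stacklevel=2,
        )
        mask = arr > 0
    else:
        thr = np.sort(pos)[::-1][target_volume_vox - 1]
        mask = arr >= thr
    if isinstance(resampled, ScalarVolume):
        return BinaryVolume(mask, resampled.voxel_size_mm, resampled.affine)
    return mask


def build_atlas(label_volumes: Sequence[LabelVolume], space_tag: str = "template",
                subject_volume_counts: dict[str, Sequence[int]] | None = None
                ) -> tuple[Atlas, list[AtlasMetricsRow]]:
    """Build the full atlas and its characterization table.

    ``label_volumes`` are per-subject artery-label volumes already in
    template space (all on one grid, sharing a name table).  One probability
    map is built per artery possessed by at least one subject.  Mean subject
    volumes default to the per-subject voxel counts of the given volumes;
    pass ``subject_volume_counts`` (artery name -> per-included-subject
    voxel counts) to use native-space counts instead.

    Mean volumes are averaged as integer voxel counts and scaled to cm^3
    once, so a cohort of voxel-identical arteries yields AVR exactly 1.0.
    """
    if not label_volumes:
        raise ValueError("at least one label volume required")
    name_table = label_volumes[0].name_table
    vox_vol = label_volumes[0].voxel_volume_mm3

    maps: dict[str, ProbabilityMap] = {}
    per_subject_counts: dict[str, list[int]] = {}
    for aid, name in sorted(name_table.items()):
        counts = [int(np.count_nonzero(lv.labels == aid)) for lv in label_volumes]
        if not any(counts):
            continue
        maps[name] = build_probability_map(name, label_volumes, label_id=aid)
        per_subject_counts[name] = [c for c in counts if c > 0]

    atlas = Atlas(maps, space_tag=space_tag)
    rows = []
    for name, pmap in maps.items():
        counts = (subject_volume_counts or {}).get(name, per_subject_counts[name])
        mean_cm3 = float(np.mean(counts)) * vox_vol / 1000.0
        rows.append(
            AtlasMetricsRow(
                artery_name=name,
                n_included=pmap.n_included,
                mean_subject_volume_cm3=mean_cm3,
                concatenated_volume_cm3=concatenated_volume(pmap),
                avr=concatenated_volume(pmap) / mean_cm3,
                dominating_volume_pct=dominating_volume(pmap, atlas),
                max_probability=max_probability(pmap),
            )
        )
    return atlas, rows


def metrics_table(rows: Sequence[AtlasMetricsRow]) -> pd.DataFrame:
    """Characterization rows as a tidy DataFrame (one artery per row)."""
    return pd.DataFrame(
        [
            {
                "artery_name": r.artery_name,
                "n_included": r.n_included,
                "mean_subject_volume_cm3": r.mean_subject_volume_cm3,
                "concatenated_volume_cm3": r.concatenated_volume_cm3,
                "avr": r.avr,
                "dominating_volume_pct": r.dominating_volume_pct,
                "max_probability": r.max_probability,
            }
            for r in rows
        ]
    )
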