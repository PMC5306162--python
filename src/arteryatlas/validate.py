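"""Leave-one-out validation, outcome categorization and summary statistics.

Automatic labelings are compared with a reference labeling per (subject,
artery) and placed in exactly one of six categories:

* ``correctly_identified_existing`` (TP): present, labeled, the labeled
  volume is pure (>= 90 % of auto-labeled voxels inside the reference
  artery by default), and the artery's segment criterion is met;
* ``correctly_identified_nonexisting`` (TN): absent and reported not found;
* ``mislabeled_existing`` (FN): present and labeled, but impure;
* ``mislabeled_nonexisting`` (FP): absent but reported found;
* ``not_identified`` (FN): present but reported not found;
* ``too_short`` (FN): present, pure, but the required segment length unmet.

Segment criteria demand a connected centerline run of a minimum physical
length (optionally inside a world-space box), emulating per-artery
requirements like "a 2 cm cervical carotid segment" scaled to phantoms.

The module also provides the exact Wilcoxon signed-rank test and Spearman
rank correlation used to compare normalization strategies across arteries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .aaim import LabelingResult, label_subject
from .atlasbuild import Atlas, build_probability_map
from .pipeline import ProcessedSubject, labels_to_template
from .volumes import LabelVolume

__all__ = [
    "SegmentCriterion",
    "OUTCOME_CATEGORIES",
    "ConfusionCounts",
    "check_criterion",
    "categorize",
    "confusion_metrics",
    "leave_one_out",
    "wilcoxon_signed_rank",
    "spearman_rho",
]

OUTCOME_CATEGORIES = (
    "correctly_identified_existing",
    "correctly_identified_nonexisting",
    "mislabeled_existing",
    "mislabeled_nonexisting",
    "not_identified",
    "too_short",
)


@dataclass
class SegmentCriterion:
    artery_name: str
    min_length_mm: float
    region_mm: tuple[Sequence[float], Sequence[float]] | None = None  # (lo, hi) world mm

    def __post_init__(self):
        if self.min_length_mm <= 0:
            raise ValueError("min_length_mm must be positive")


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn_mislabeled: int = 0
    fn_not_identified: int = 0
    fn_too_short: int = 0

    @property
    def fn_total(self) -> int:
        return self.fn_mislabeled + self.fn_not_identified + self.fn_too_short

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn_total

    def add(self, category: str) -> None:
        attr = {
            "correctly_identified_existing": "tp",
            "correctly_identified_nonexisting": "tn",
            "mislabeled_nonexisting": "fp",
            "mislabeled_existing": "fn_mislabeled",
            "not_identified": "fn_not_identified",
            "too_short": "fn_too_short",
        }[category]
        setattr(self, attr, getattr(self, attr) + 1)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def confusion_metrics(c: ConfusionCounts) -> tuple[int, int | None, int]:
    """(sensitivity %, specificity % or None, accuracy %), integer-rounded
    half up.  Specificity is undefined without any true negative or false
    positive."""
    sens = _round_half_up(100.0 * c.tp / (c.tp + c.fn_total)) if c.tp + c.fn_total else None
    spec = _round_half_up(100.0 * c.tn / (c.tn + c.fp)) if c.tn + c.fp else None
    acc = _round_half_up(100.0 * (c.tp + c.tn) / c.total)
    return sens, spec, acc


def _longest_run_mm(voxels: Sequence[tuple[int, int, int]], voxel_size_mm) -> float:
    """Longest connected centerline run: weighted-diameter of the 26-adjacency
    graph (diagonal steps scaled by geometry) plus one voxel extent, so a
    straight run of n voxels measures n times the voxel size.  Exact on trees
    via a double Dijkstra sweep per component."""
    if not voxels:
        return 0.0
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    vset = set(map(tuple, voxels))
    g = nx.Graph()
    g.add_nodes_from(vset)
    offsets = [
        d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
    ]
    for v in vset:
        for d in offsets:
            n = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if n in vset and not g.has_edge(v, n):
                g.add_edge(v, n, weight=float(np.linalg.norm(np.array(d) * vox)))
    best = 0.0
    for comp in nx.connected_components(g):
        start = next(iter(comp))
        d0 = nx.single_source_dijkstra_path_length(g, start)
        far = max(d0, key=d0.get)
        d1 = nx.single_source_dijkstra_path_length(g, far)
        best = max(best, max(d1.values()))
    return best + float(vox.mean())


def check_criterion(voxels: Sequence[tuple[int, int, int]], voxel_size_mm,
                    criterion: SegmentCriterion, affine: np.ndarray | None = None) -> bool:
    """True iff the artery's labeled centerline voxels contain a connected
    run of path length >= ``min_length_mm`` lying inside the criterion region
    (whole grid when no region is given)."""
    voxels = list(voxels)
    if criterion.region_mm is not None:
        vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
        pts = np.asarray(voxels, dtype=float)
        if affine is not None:
            mm = pts @ affine[:3, :3].T + affine[:3, 3]
        else:
            mm = pts * vox
        lo, hi = (np.asarray(b, dtype=float) for b in criterion.region_mm)
        keep = np.all((mm >= lo) & (mm <= hi), axis=1)
        voxels = [v for v, k in zip(voxels, keep) if k]
    return _longest_run_mm(voxels, voxel_size_mm) >= criterion.min_length_mm


def categorize(auto: LabelingResult, truth: LabelVolume,
               presence: Mapping[str, bool],
               criteria: Mapping[str, SegmentCriterion] | None = None,
               purity_threshold: float = 0.9) -> dict[str, str]:
    """Assign each artery exactly one of the six outcome categories.

    ``truth`` is the reference labeling on the same grid as the automatic
    labeling; ``presence`` says which arteries exist in the reference.  The
    purity surrogate for the study's case-by-case mislabeling judgement is
    the fraction of auto-labeled voxels lying inside the reference artery.
    """
    if auto.label_volume.shape != truth.shape:
        raise ValueError("automatic and reference label volumes must share a grid")
    criteria = criteria or {}
    truth_id = {name: aid for aid, name in truth.name_table.items()}
    auto_id = {name: aid for aid, name in auto.label_volume.name_table.items()}

    out: dict[str, str] = {}
    for name in auto.statuses:
        present = bool(presence.get(name, False))
        found = auto.statuses[name] == "found"
        if not present:
            out[name] = "mislabeled_nonexisting" if found else "correctly_identified_nonexisting"
            continue
        if not found:
            out[name] = "not_identified"
            continue
        auto_vox = auto.label_volume.labels == auto_id[name]
        n_auto = int(np.count_nonzero(auto_vox))
        if n_auto == 0:
            out[name] = "not_identified"
            continue
        inside = int(np.count_nonzero(auto_vox & (truth.labels == truth_id.get(name, -1))))
        if inside / n_auto < purity_threshold:
            out[name] = "mislabeled_existing"
            continue
        crit = criteria.get(name)
        if crit is not None and not check_criterion(
            auto.artery_skeleton_voxels(name),
            auto.label_volume.voxel_size_mm,
            crit,
            affine=auto.label_volume.affine,
        ):
            out[name] = "too_short"
        else:
            out[name] = "correctly_identified_existing"
    return out


# ---------------------------------------------------------------------------
# Leave-one-out harness


def leave_one_out(processed: Sequence[ProcessedSubject],
                  criteria: Mapping[str, SegmentCriterion] | None = None,
                  tau: float = 0.1, purity_threshold: float = 0.9,
                  mode: str = "nonlinear") -> tuple[dict[str, ConfusionCounts], pd.DataFrame]:
    """Rebuild the atlas without each subject, label that subject with the
    reduced atlas, and categorize against the subject's reference labeling.

    Returns per-artery confusion counts and a summary table whose last
    column holds sensitivity/specificity/accuracy; the overall figure of
    merit is the unweighted mean of per-artery accuracies.
    """
    processed = list(processed)
    if len(processed) < 2:
        raise ValueError("leave-one-out needs at least two subjects")

    name_table = processed[0].reference_labels.name_table
    names = [name_table[k] for k in sorted(name_table)]
    template_labels = [labels_to_template(p, mode=mode) for p in processed]

    # per-artery stacked counts so each held-out atlas is a subtraction
    sums: dict[str, np.ndarray] = {}
    per_subject: dict[str, list[np.ndarray | None]] = {n: [] for n in names}
    for aid, name in sorted(name_table.items()):
        total = None
        for tl in template_labels:
            b = (tl.labels == aid).astype(np.int32)
            per_subject[name].append(b if b.any() else None)
            total = b if total is None else total + b
        sums[name] = total

    counts = {n: ConfusionCounts() for n in names}
    grid = processed[0].reference_labels
    for i, proc in enumerate(processed):
        maps = {}
        for name in names:
            left = sums[name] - (
                per_subject[name][i] if per_subject[name][i] is not None else 0
            )
            n_inc = sum(
                1 for j, b in enumerate(per_subject[name]) if j != i and b is not None
            )
            if n_inc == 0:
                continue
            maps[name] = build_probability_map_from_sum(
                name, left, n_inc, grid.voxel_size_mm, grid.affine
            )
        atlas = Atlas(maps, space_tag=mode)
        transform = (
            proc.subject.transform
            if mode == "nonlinear"
            else _rigid_of(proc.subject.transform)
        )
        result = label_subject(
            proc.subject.angio, atlas, transform, tau=tau,
            mask=proc.mask, skeleton=proc.skeleton,
        )
        cats = categorize(
            result, proc.reference_labels, proc.reference_presence,
            criteria=criteria, purity_threshold=purity_threshold,
        )
        for name in names:
            if name in cats:
                counts[name].add(cats[name])
            else:  # artery absent from the reduced atlas: AAIM cannot find it
                counts[name].add(
                    "not_identified" if proc.reference_presence.get(name)
                    else "correctly_identified_nonexisting"
                )

    rows = []
    for name in names:
        c = counts[name]
        sens, spec, acc = confusion_metrics(c)
        rows.append(
            {
                "artery_name": name, "tp": c.tp, "tn": c.tn, "fp": c.fp,
                "fn_mislabeled": c.fn_mislabeled,
                "fn_not_identified": c.fn_not_identified,
                "fn_too_short": c.fn_too_short,
                "sensitivity": sens, "specificity": spec, "accuracy": acc,
            }
        )
    summary = pd.DataFrame(rows)
    summary.attrs["mean_accuracy"] = float(summary["accuracy"].mean())
    return counts, summary


def _rigid_of(transform):
    from .volumes import rigid_only

    return rigid_only(transform)


def build_probability_map_from_sum(name, summed, n_included, voxel_size_mm, affine):
    from .atlasbuild import ProbabilityMap

    return ProbabilityMap(name, summed.astype(float) / n_included, n_included,
                          voxel_size_mm, affine)


# ---------------------------------------------------------------------------
# Statistics


def wilcoxon_signed_rank(paired_a: Sequence[float], paired_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value.

    Zero differences are dropped; tied absolute differences receive average
    ranks.  For n <= 25 remaining pairs the null distribution of W+ is
    enumerated exactly (subset-sum convolution over doubled ranks, which are
    integers even with ties); beyond that a normal approximation with tie
    correction is used.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if a.size < 5:
        raise ValueError("at least 5 pairs required")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        r2 = np.rint(ranks * 2).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            counts[r:] = counts[r:] + counts[: total - r + 1]
        denom = 2.0**n
        w2 = int(round(w_plus * 2))
        p_le = counts[: w2 + 1].sum() / denom
        p_ge = counts[w2:].sum() / denom
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average-ranked
    values (ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("inputs must be equal-length 1D sequences of length >= 2")
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
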