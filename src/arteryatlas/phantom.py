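"""Synthetic multi-subject angiographic cohorts with known ground truth.

The generator emulates the statistical structure an arterial-atlas pipeline
assumes about a real angiographic cohort:

* a set of named tubular arteries in a common template space, each with a
  population prevalence (communicating arteries are absent in many subjects);
* per-subject anatomy modelled as a smooth random non-linear deformation of
  the template composed with a small rigid misalignment;
* angiographic contrast with a flat tube core, a one-voxel cosine rim
  falloff (so fractional-maximum thresholding recovers the lumen to within a
  voxel of the true radius) and additive Gaussian background noise;
* per-subject ground-truth artery label volumes and the exact generating
  transform, so downstream normalization can be studied against truth.

It does not simulate haemodynamics, and the default geometry is a
topologically circle-of-Willis-like arrangement of tubes rather than a
faithful anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import (
    LabelVolume,
    ScalarVolume,
    SubjectTransform,
    apply_transform,
    default_affine,
)

__all__ = [
    "ArterySpec",
    "CohortConfig",
    "SyntheticSubject",
    "render_template",
    "generate_cohort",
    "default_artery_specs",
    "default_criteria",
]


@dataclass
class ArterySpec:
    """One named tubular artery in template millimetre coordinates."""

    name: str
    centerline: np.ndarray  # (n, 3) control points, mm
    radius_mm: float
    prevalence: float = 1.0
    peak_intensity: float = 1.0

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValueError(f"{self.name}: centerline must be (n, 3)")
        if len(self.centerline) < 2:
            raise ValueError(f"{self.name}: centerline needs >= 2 control points")
        if np.any(np.all(np.diff(self.centerline, axis=0) == 0, axis=1)):
            raise ValueError(f"{self.name}: consecutive control points must differ")
        if self.radius_mm <= 0:
            raise ValueError(f"{self.name}: radius must be positive")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"{self.name}: prevalence must lie in [0, 1]")
        if self.peak_intensity <= 0:
            raise ValueError(f"{self.name}: peak intensity must be positive")


@dataclass
class CohortConfig:
    n_subjects: int
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 0.7
    deform_amplitude_mm: float = 2.0
    deform_smoothness_mm: float = 6.0
    rigid_jitter: tuple[float, float] = (3.0, 1.5)  # max rotation deg, translation mm
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 2:
            raise ValueError("grid_shape must be three integers >= 2")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.deform_amplitude_mm < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise must be non-negative")
        if self.deform_smoothness_mm <= 0:
            raise ValueError("deform_smoothness_mm must be positive")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_size_mm)

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.array(self.grid_shape) - 1) * self.voxel_size_mm


@dataclass
class SyntheticSubject:
    """One simulated subject: image, truth labels, presence flags, and the
    exact transform whose forward application normalizes it to template."""

    subject_id: str
    angio: ScalarVolume
    truth_labels: LabelVolume
    presence: dict[str, bool]
    transform: SubjectTransform


def _densify(centerline: np.ndarray, step_mm: float) -> np.ndarray:
    pts = [centerline[:1]]
    for a, b in zip(centerline[:-1], centerline[1:]):
        seg = b - a
        n = max(2, int(np.ceil(np.linalg.norm(seg) / step_mm)) + 1)
        t = np.linspace(0.0, 1.0, n)[1:, None]
        pts.append(a + t * seg)
    return np.concatenate(pts, axis=0)


def _radial_profile(dist: np.ndarray, radius: float, h: float) -> np.ndarray:
    """Flat core with a cosine falloff of width one voxel centred on the wall:
    1 inside r - h/2, 0 beyond r + h/2."""
    t = np.clip((dist - (radius - h / 2)) / h, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def render_template(
    specs: Sequence[ArterySpec],
    config: CohortConfig,
    present: Sequence[bool] | None = None,
) -> tuple[ScalarVolume, LabelVolume]:
    """Render tube intensities and labels onto the template grid.

    ``present`` masks out absent arteries while keeping the label ids of the
    full spec list (id = 1-based position).  Intensity is the sum of per-tube
    contributions; a voxel inside several tubes is labeled with the artery
    whose centerline is nearest (ties to the lower id).
    """
    if present is None:
        present = [True] * len(specs)
    shape = config.grid_shape
    vox = config.voxel_size_mm
    extent = config.extent_mm
    for spec in specs:
        if np.any(spec.centerline < 0) or np.any(spec.centerline > extent):
            raise ValueError(f"artery '{spec.name}' centerline leaves the grid extent")

    intensity = np.zeros(shape, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    best_dist = np.full(shape, np.inf)
    name_table = {i + 1: s.name for i, s in enumerate(specs)}

    grid_idx = None
    for aid, (spec, here) in enumerate(zip(specs, present), start=1):
        if not here:
            continue
        dense = _densify(spec.centerline, 0.25 * vox)
        reach = spec.radius_mm + 1.5 * vox
        lo = np.maximum(np.floor((dense.min(0) - reach) / vox).astype(int), 0)
        hi = np.minimum(np.ceil((dense.max(0) + reach) / vox).astype(int) + 1, shape)
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        if grid_idx is None:
            grid_idx = np.indices(shape, dtype=float)
        pts = np.stack([grid_idx[c][sub] for c in range(3)], axis=-1) * vox
        dist, _ = cKDTree(dense).query(pts.reshape(-1, 3))
        dist = dist.reshape(pts.shape[:-1])
        intensity[sub] += spec.peak_intensity * _radial_profile(dist, spec.radius_mm, vox)
        inside = dist <= spec.radius_mm
        take = inside & (dist < best_dist[sub])
        labels[sub] = np.where(take, aid, labels[sub])
        best_dist[sub] = np.where(take, dist, best_dist[sub])

    affine = config.affine
    return (
        ScalarVolume(intensity, vox, affine),
        LabelVolume(labels, name_table, vox, affine),
    )


def _random_rigid(rng: np.random.Generator, config: CohortConfig) -> np.ndarray:
    """Small random rotation about the grid centre plus a random translation."""
    max_rot, max_trans = config.rigid_jitter
    angles = np.deg2rad(rng.uniform(-max_rot, max_rot, size=3))
    trans = rng.uniform(-max_trans, max_trans, size=3)
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rot = rz @ ry @ rx
    centre = config.extent_mm / 2
    out = np.eye(4)
    out[:3, :3] = rot
    out[:3, 3] = centre - rot @ centre + trans
    return out


def _random_displacement(rng: np.random.Generator, config: CohortConfig) -> np.ndarray | None:
    """Gaussian-filtered white noise rescaled so the largest displacement
    vector has magnitude ``deform_amplitude_mm``."""
    if config.deform_amplitude_mm == 0:
        return None
    sigma_vox = config.deform_smoothness_mm / config.voxel_size_mm
    raw = rng.standard_normal(size=(*config.grid_shape, 3))
    for c in range(3):
        raw[..., c] = ndimage.gaussian_filter(raw[..., c], sigma=sigma_vox)
    mags = np.linalg.norm(raw, axis=-1)
    peak = mags.max()
    if peak > 0:
        raw *= config.deform_amplitude_mm / peak
    return raw


def generate_cohort(specs: Sequence[ArterySpec], config: CohortConfig) -> list[SyntheticSubject]:
    """Simulate a cohort: per subject, sample artery presence by prevalence,
    draw a smooth deformation + rigid jitter, warp the template into subject
    space (intensities trilinear, labels nearest-neighbour) and add noise.

    All randomness derives from ``config.seed``; identical config and seed
    give a bit-identical cohort.
    """
    if not specs:
        raise ValueError("at least one artery spec is required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("artery names must be unique")

    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    subjects = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        present = rng.random(len(specs)) < np.array([s.prevalence for s in specs])
        rigid = _random_rigid(rng, config)
        disp = _random_displacement(rng, config)
        transform = SubjectTransform(
            rigid, disp, config.affine if disp is not None else None
        )

        template_ai, template_labels = render_template(specs, config, present)
        angio = apply_transform(template_ai, transform, direction="inverse", interp="linear")
        truth = apply_transform(template_labels, transform, direction="inverse", interp="nearest")
        if config.noise_sd > 0:
            noisy = angio.values + rng.normal(0.0, config.noise_sd, size=angio.shape)
            angio = ScalarVolume(np.clip(noisy, 0.0, None), angio.voxel_size_mm, angio.affine)
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{i + 1:03d}",
                angio=angio,
                truth_labels=truth,
                presence=dict(zip(names, map(bool, present))),
                transform=transform,
            )
        )
    return subjects


def default_artery_specs(config: CohortConfig) -> list[ArterySpec]:
    """An 11-artery circle-of-Willis-like phantom scaled to the grid extent.

    Bilateral internal carotid (ICA), middle cerebral (MCA), anterior
    cerebral (ACA), posterior cerebral (PCA) and posterior communicating
    (PCoA) tubes plus a basilar artery (BA).  Prevalences mirror a
    population cohort: ICA/MCA/BA effectively always present, ACA ~0.94,
    PCoA ~0.38.  PCoA is rendered thinner and fainter than the trunks (slow flow).
    """
    e = config.extent_mm
    def p(x, y, z):
        return [x * e[0], y * e[1], z * e[2]]

    specs = [
        ArterySpec("ICA_R", [p(0.67, 0.36, 0.14), p(0.67, 0.40, 0.54)], 1.6, 1.0, 1.0),
        ArterySpec("ICA_L", [p(0.33, 0.36, 0.14), p(0.33, 0.40, 0.54)], 1.6, 1.0, 1.0),
        ArterySpec("BA", [p(0.50, 0.67, 0.14), p(0.50, 0.67, 0.50)], 1.3, 1.0, 0.9),
        ArterySpec("PCA_R", [p(0.50, 0.67, 0.50), p(0.78, 0.79, 0.62)], 1.0, 0.98, 0.8),
        ArterySpec("PCA_L", [p(0.50, 0.67, 0.50), p(0.22, 0.79, 0.62)], 1.0, 0.98, 0.8),
        ArterySpec("MCA_R", [p(0.67, 0.40, 0.54), p(0.87, 0.46, 0.65)], 1.1, 1.0, 0.9),
        ArterySpec("MCA_L", [p(0.33, 0.40, 0.54), p(0.13, 0.46, 0.65)], 1.1, 1.0, 0.9),
        ArterySpec("ACA_R", [p(0.67, 0.40, 0.54), p(0.555, 0.46, 0.72)], 0.9, 0.94, 0.8),
        ArterySpec("ACA_L", [p(0.33, 0.40, 0.54), p(0.445, 0.46, 0.72)], 0.9, 0.94, 0.8),
        # PCoA runs from the ICA trunk to a point on the PCA centerline.
        ArterySpec("PCoA_R", [p(0.67, 0.395, 0.49), p(0.598, 0.712, 0.542)], 1.1, 0.38, 0.8),
        ArterySpec("PCoA_L", [p(0.33, 0.395, 0.49), p(0.402, 0.712, 0.542)], 1.1, 0.38, 0.8),
    ]
    return specs


def default_criteria():
    """Per-artery segment criteria for the default phantom geometry.

    Mirrors the structure of clinical acceptance rules ("a 2 cm cervical
    carotid segment", "a 5 mm A1 segment", ...) scaled to the phantom: the
    labeled centerline must contain a connected run of the given length.
    Trunks demand longer runs than communicating and distal segments.
    """
    from .validate import SegmentCriterion

    lengths = {
        "ICA_R": 8.0, "ICA_L": 8.0, "BA": 8.0,
        "PCA_R": 4.0, "PCA_L": 4.0, "MCA_R": 4.0, "MCA_L": 4.0,
        "ACA_R": 3.0, "ACA_L": 3.0, "PCoA_R": 4.0, "PCoA_L": 4.0,
    }
    return {name: SegmentCriterion(name, mm) for name, mm in lengths.items()}
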