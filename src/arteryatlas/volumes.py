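"""Volume containers, NIfTI I/O, smoothing, thresholding and spatial transforms.

The package works with three grid-aligned volume types: scalar angiographic
images, binary vessel masks, and integer artery-label volumes.  All three carry
the same grid metadata (isotropic-ish voxel size and a 4x4 voxel-index to
world-millimetre affine).  Spatial normalization is expressed through
:class:`SubjectTransform`, which composes an invertible affine with an optional
smooth displacement field; it stands in for the non-linear normalization of an
angiographic study (template estimation itself is out of scope — the transforms
are known, e.g. produced by the phantom generator, or reduced to their rigid
part for the rigid-body comparison).

Conventions
-----------
* Voxel indices are 0-based; world coordinates are millimetres via the affine.
* ``SubjectTransform`` stores the *template -> subject* point map
  ``m(x) = A @ x + u(x)`` with ``u`` (mm) sampled on the template grid.
  Applying it in the ``forward`` direction resamples a subject-space volume
  onto the template grid (the normalization used for atlas building), which
  needs exactly ``m``.  The ``inverse`` direction (template -> subject space)
  inverts ``A`` exactly and the displacement by fixed-point iteration.
* Subject and template volumes share one grid in this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.linalg import polar

__all__ = [
    "ScalarVolume",
    "BinaryVolume",
    "LabelVolume",
    "SubjectTransform",
    "VolumeFormatError",
    "default_affine",
    "read_volume",
    "read_label_volume",
    "write_volume",
    "box_smooth",
    "threshold_binarize",
    "apply_transform",
    "rigid_only",
    "map_points_template_to_subject",
    "map_points_subject_to_template",
]


class VolumeFormatError(RuntimeError):
    """Raised when a file cannot be parsed as a NIfTI volume."""


def default_affine(voxel_size_mm: float | tuple[float, float, float]) -> np.ndarray:
    """Diagonal index->mm affine with the origin at voxel (0, 0, 0)."""
    v = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    aff = np.eye(4)
    aff[:3, :3] = np.diag(v)
    return aff


def _check_grid(values: np.ndarray, voxel_size_mm, affine: np.ndarray):
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"expected a 3D grid, got shape {values.shape}")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,)).copy()
    if np.any(vox <= 0):
        raise ValueError("voxel size must be positive")
    scales = np.linalg.norm(affine[:3, :3], axis=0)
    if not np.allclose(scales, vox, rtol=1e-3, atol=1e-6):
        raise ValueError(
            f"voxel_size_mm {vox} inconsistent with affine column norms {scales}"
        )
    return values, vox, affine


@dataclass
class ScalarVolume:
    """A 3D non-negative intensity grid (the angiographic image)."""

    values: np.ndarray
    voxel_size_mm: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.values, self.voxel_size_mm, self.affine = _check_grid(
            np.asarray(self.values, dtype=float), self.voxel_size_mm, self.affine
        )

    @classmethod
    def from_array(cls, values, voxel_size_mm=1.0, affine=None) -> "ScalarVolume":
        if affine is None:
            affine = default_affine(voxel_size_mm)
        return cls(values, voxel_size_mm, affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class BinaryVolume:
    """Binary vessel mask sharing the grid metadata of its source volume."""

    mask: np.ndarray
    voxel_size_mm: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.mask, self.voxel_size_mm, self.affine = _check_grid(
            np.asarray(self.mask).astype(bool), self.voxel_size_mm, self.affine
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class LabelVolume:
    """Integer artery-label grid; 0 is background, ids index ``name_table``."""

    labels: np.ndarray
    name_table: dict[int, str]
    voxel_size_mm: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.rint(labels)):
                raise ValueError("label grid must be integer-valued")
            labels = np.rint(labels).astype(np.int32)
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels, self.voxel_size_mm, self.affine = _check_grid(
            labels, self.voxel_size_mm, self.affine
        )
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.name_table)
        if missing:
            raise ValueError(f"label ids {sorted(missing)} missing from name_table")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def binary(self, label_id: int) -> np.ndarray:
        return self.labels == label_id


@dataclass
class SubjectTransform:
    """Template->subject point map: ``m(x) = affine_component @ x + u(x)``.

    ``displacement_field`` is an ``(nx, ny, nz, 3)`` array of millimetre
    offsets sampled on the template grid (``field_affine`` maps its voxel
    indices to mm); ``None`` means the transform is purely affine.
    """

    affine_component: np.ndarray
    displacement_field: np.ndarray | None = None
    field_affine: np.ndarray | None = None

    def __post_init__(self):
        self.affine_component = np.asarray(self.affine_component, dtype=float)
        if self.affine_component.shape != (4, 4):
            raise ValueError("affine_component must be 4x4")
        if abs(np.linalg.det(self.affine_component[:3, :3])) < 1e-12:
            raise ValueError("affine_component is singular")
        if self.displacement_field is not None:
            f = np.asarray(self.displacement_field, dtype=float)
            if f.ndim != 4 or f.shape[-1] != 3:
                raise ValueError("displacement_field must be (nx, ny, nz, 3)")
            self.displacement_field = f
            if self.field_affine is None:
                raise ValueError("field_affine required with a displacement field")
            self.field_affine = np.asarray(self.field_affine, dtype=float)

    @property
    def is_nonlinear(self) -> bool:
        return self.displacement_field is not None

    @classmethod
    def identity(cls) -> "SubjectTransform":
        return cls(np.eye(4))


# ---------------------------------------------------------------------------
# I/O


def read_volume(path) -> ScalarVolume:
    """Read a NIfTI scalar volume.

    Raises ``FileNotFoundError`` for a missing path and
    :class:`VolumeFormatError` for a file nibabel cannot parse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # malformed file
        raise VolumeFormatError(f"cannot read NIfTI volume: {path}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"expected 3D data in {path}, got {data.shape}")
    affine = img.affine
    vox = np.linalg.norm(affine[:3, :3], axis=0)
    return ScalarVolume(np.asarray(data, dtype=float), vox, affine)


def read_label_volume(path, name_table: Mapping[int, str] | None = None) -> LabelVolume:
    """Read a NIfTI label volume; ``name_table`` defaults to a JSON sidecar
    (``<stem>.json`` with ``{"name_table": {...}}``) or synthesized names."""
    sv = read_volume(path)
    labels = np.rint(sv.values).astype(np.int32)
    if name_table is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            name_table = {int(k): v for k, v in meta.get("name_table", {}).items()}
        else:
            name_table = {int(k): f"label_{int(k)}" for k in np.unique(labels) if k != 0}
    return LabelVolume(labels, dict(name_table), sv.voxel_size_mm, sv.affine)


def _sidecar_path(path) -> Path:
    path = Path(path)
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(stem + ".json")


def write_volume(volume, path) -> None:
    """Write a Scalar/Binary/Label volume as NIfTI (label names to a sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, LabelVolume):
        img = nib.Nifti1Image(volume.labels.astype(np.int32), volume.affine)
        img.set_data_dtype(np.int32)
        nib.save(img, str(path))
        _sidecar_path(path).write_text(
            json.dumps({"name_table": {str(k): v for k, v in volume.name_table.items()}})
        )
    elif isinstance(volume, BinaryVolume):
        img = nib.Nifti1Image(volume.mask.astype(np.uint8), volume.affine)
        img.set_data_dtype(np.uint8)
        nib.save(img, str(path))
    else:
        img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64), volume.affine)
        img.set_data_dtype(np.float64)
        nib.save(img, str(path))


def write_displacement_field(transform: SubjectTransform, path) -> None:
    """Displacement field as 4D NIfTI (3 mm-components on the template grid)."""
    if transform.displacement_field is None:
        raise ValueError("transform has no displacement field")
    img = nib.Nifti1Image(
        np.asarray(transform.displacement_field, dtype=np.float64), transform.field_affine
    )
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Smoothing and thresholding


def box_smooth(vol: ScalarVolume, width_vox: int = 3) -> ScalarVolume:
    """Low-pass box filter: each voxel becomes the mean of its ``width³``
    neighbourhood, with zero-padding at the borders (vessels are interior,
    and the fixed border rule keeps results bit-reproducible)."""
    if width_vox < 1 or width_vox % 2 == 0:
        raise ValueError("box filter width must be an odd positive integer")
    out = ndimage.uniform_filter(vol.values, size=width_vox, mode="constant", cval=0.0)
    return replace(vol, values=out)


def threshold_binarize(vol: ScalarVolume, fraction: float = 0.18) -> BinaryVolume:
    """Binarize at ``fraction`` of the global maximum intensity (inclusive >=).

    The 18 % default recovers the full vessel lumen without pulling in
    neighbouring static tissue on angiographic contrast.  The input is
    expected to be the smoothed image; the maximum is taken from it.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    vmax = float(vol.values.max())
    if vmax <= 0:
        raise ValueError("volume has no positive intensities — no vessel signal")
    mask = vol.values >= fraction * vmax
    return BinaryVolume(mask, vol.voxel_size_mm, vol.affine)


# ---------------------------------------------------------------------------
# Transforms


def _apply_affine(affine: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return pts @ affine[:3, :3].T + affine[:3, 3]


def _sample_field(field: np.ndarray, field_affine: np.ndarray, pts_mm: np.ndarray) -> np.ndarray:
    """Trilinearly sample a (nx,ny,nz,3) mm displacement field at mm points.

    Edge handling is 'nearest' so points marginally outside the grid see the
    boundary value instead of an artificial zero.
    """
    inv = np.linalg.inv(field_affine)
    vox = _apply_affine(inv, pts_mm).T  # (3, N)
    out = np.empty_like(pts_mm)
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(field[..., c], vox, order=1, mode="nearest")
    return out


def map_points_template_to_subject(transform: SubjectTransform, pts_mm: np.ndarray) -> np.ndarray:
    """Evaluate the stored point map ``m(x) = A x + u(x)`` at template points."""
    pts_mm = np.atleast_2d(np.asarray(pts_mm, dtype=float))
    out = _apply_affine(transform.affine_component, pts_mm)
    if transform.displacement_field is not None:
        out = out + _sample_field(transform.displacement_field, transform.field_affine, pts_mm)
    return out


def map_points_subject_to_template(
    transform: SubjectTransform, pts_mm: np.ndarray, n_iter: int = 10
) -> np.ndarray:
    """Approximate inverse point map by fixed-point iteration.

    Solves ``A y + u(y) = p`` via ``y <- A^{-1}(p - u(y))``; exact for purely
    affine transforms, and convergent for displacement fields whose gradient
    is below 1 (smooth, small-amplitude warps).
    """
    pts_mm = np.atleast_2d(np.asarray(pts_mm, dtype=float))
    ainv = np.linalg.inv(transform.affine_component)
    y = _apply_affine(ainv, pts_mm)
    if transform.displacement_field is None:
        return y
    for _ in range(n_iter):
        u = _sample_field(transform.displacement_field, transform.field_affine, y)
        y = _apply_affine(ainv, pts_mm - u)
    return y


def _grid_points_mm(shape, affine) -> np.ndarray:
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    return _apply_affine(affine, idx)


def apply_transform(vol, transform: SubjectTransform, direction: str = "forward",
                    interp: str | None = None, require_nonlinear: bool = False):
    """Resample a volume through a subject transform.

    direction='forward'  : subject-space volume -> template grid (normalization).
    direction='inverse'  : template-space volume -> subject grid.

    Intensities are interpolated linearly, labels and masks nearest-neighbour
    (labels must stay integral); pass ``interp`` to override.  The output grid
    equals the input grid (subject and template share a grid here).
    """
    if direction not in ("forward", "inverse"):
        raise ValueError("direction must be 'forward' or 'inverse'")
    if require_nonlinear and transform.displacement_field is None:
        raise ValueError("non-linear transform requested but displacement field missing")

    if isinstance(vol, LabelVolume):
        data, default_interp = vol.labels.astype(np.float64), "nearest"
    elif isinstance(vol, BinaryVolume):
        data, default_interp = vol.mask.astype(np.float64), "nearest"
    else:
        data, default_interp = vol.values, "linear"
    interp = interp or default_interp
    order = {"linear": 1, "nearest": 0}[interp]

    pts = _grid_points_mm(data.shape, vol.affine)
    if direction == "forward":
        src = map_points_template_to_subject(transform, pts)
    else:
        src = map_points_subject_to_template(transform, pts)
    src_vox = _apply_affine(np.linalg.inv(vol.affine), src).T
    out = ndimage.map_coordinates(data, src_vox, order=order, mode="constant", cval=0.0)
    out = out.reshape(data.shape)

    if isinstance(vol, LabelVolume):
        return LabelVolume(np.rint(out).astype(np.int32), vol.name_table,
                           vol.voxel_size_mm, vol.affine)
    if isinstance(vol, BinaryVolume):
        return BinaryVolume(out > 0.5, vol.voxel_size_mm, vol.affine)
    return replace(vol, values=out)


def rigid_only(transform: SubjectTransform) -> SubjectTransform:
    """Reduce a transform to its nearest rotation + translation.

    Drops the displacement field and replaces the 3x3 affine block by the
    orthogonal factor of its polar decomposition (scale and shear discarded);
    the translation column is kept.
    """
    a3 = transform.affine_component[:3, :3]
    if abs(np.linalg.det(a3)) < 1e-12:
        raise ValueError("affine component is singular")
    rot, _ = polar(a3)
    out = np.eye(4)
    out[:3, :3] = rot
    out[:3, 3] = transform.affine_component[:3, 3]
    return SubjectTransform(out)
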