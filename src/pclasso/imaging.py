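"""Parametric image I/O, binding-ratio computation and voxel-matrix assembly.

Images are 3-D volumes already resampled into a common labeled template space;
no registration or warping happens here.  A binding-ratio (BR) image is a
static activity image divided by the mean activity in a nonspecific reference
region, giving a dimensionless proxy for specific tracer binding.

For pattern analysis each labeled ROI is flattened into a subject-by-voxel
matrix: every template voxel is a variable, every subject an observation.
Column order is lexicographic over the (i, j, k) template indices so the
flattening is reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import ComputationError, FormatError, ShapeError, ValidationError

SIDES = ("left", "right", "better", "worse")


@dataclass
class ParametricImage:
    """A 3-D parametric (activity or binding-ratio) volume with spatial metadata."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str | None = None
    side: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ShapeError(f"image must be 3-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("image contains non-finite voxel values")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ShapeError("affine must be 4x4")
        if self.side is not None and self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


def read_image(path, template=None) -> ParametricImage:
    """Load a NIfTI-1 volume; optionally validate its grid against a template."""
    try:
        img = nib.load(str(path))
        values = np.asarray(img.get_fdata(), dtype=float)
    except (nib.filebasedimages.ImageFileError, OSError, EOFError, ValueError) as exc:
        raise FormatError(f"could not read NIfTI image {path}: {exc}") from exc
    if values.ndim == 4 and values.shape[3] == 1:
        values = values[..., 0]
    if values.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {values.shape}")
    if template is not None and values.shape != tuple(template.grid_shape):
        raise ShapeError(
            f"{path}: image grid {values.shape} does not match template grid "
            f"{tuple(template.grid_shape)}"
        )
    return ParametricImage(values=values, affine=np.asarray(img.affine))


def write_image(image: ParametricImage, path) -> None:
    """Write a volume as float64 NIfTI-1 (lossless round-trip of values)."""
    nii = nib.Nifti1Image(image.values.astype(np.float64), image.affine)
    nib.save(nii, str(path))


def compute_br(
    activity_image: ParametricImage, reference_mask: np.ndarray
) -> ParametricImage:
    """Binding-ratio image: voxel activity divided by mean reference activity.

    ``reference_mask`` is a boolean (or 0/1 integer) array on the same grid.
    The reference statistics used are attached as ``.reference_stats``.
    """
    mask = np.asarray(reference_mask).astype(bool)
    if mask.shape != activity_image.shape:
        raise ShapeError(
            f"reference mask shape {mask.shape} does not match image {activity_image.shape}"
        )
    n_ref = int(mask.sum())
    if n_ref == 0:
        raise ValidationError("reference mask is empty")
    ref_mean = float(activity_image.values[mask].mean())
    if ref_mean <= 0:
        raise ComputationError(f"mean reference activity must be positive, got {ref_mean}")
    br = ParametricImage(
        values=activity_image.values / ref_mean,
        affine=activity_image.affine,
        subject_id=activity_image.subject_id,
        side=activity_image.side,
    )
    br.reference_stats = {"mean": ref_mean, "n_voxels": n_ref}  # type: ignore[attr-defined]
    return br


@dataclass
class VoxelMatrix:
    """Subject-by-voxel matrix over one labeled ROI.

    ``data`` has one row per subject, one column per ROI voxel; ``voxel_index``
    maps column ``c`` to the template coordinate ``voxel_index[c] = (i, j, k)``.
    """

    data: np.ndarray
    voxel_index: np.ndarray
    roi_label: int
    side: str | None
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.data.ndim != 2:
            raise ShapeError("voxel matrix must be 2-D")
        if self.voxel_index.shape != (self.data.shape[1], 3):
            raise ShapeError("voxel_index must be (V, 3) matching the data columns")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ShapeError("subject_ids length must match the number of rows")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def subset(self, row_indices) -> "VoxelMatrix":
        idx = np.asarray(row_indices)
        return replace(
            self,
            data=self.data[idx],
            subject_ids=tuple(np.asarray(self.subject_ids, dtype=object)[idx]),
        )


def extract_voxel_matrix(
    images: Sequence[ParametricImage], template, roi_label: int
) -> VoxelMatrix:
    """Flatten one ROI of each image into a row of a subject-by-voxel matrix."""
    if len(images) == 0:
        raise ValidationError("need at least one image")
    idx = template.roi_indices(roi_label)  # lexicographic (i,j,k), validated there
    grid = tuple(template.grid_shape)
    rows = []
    for img in images:
        if img.shape != grid:
            raise ShapeError(
                f"image grid {img.shape} does not match template grid {grid}"
            )
        rows.append(img.values[idx[:, 0], idx[:, 1], idx[:, 2]])
    sides = {img.side for img in images}
    side = sides.pop() if len(sides) == 1 else None
    subject_ids = tuple(
        img.subject_id if img.subject_id is not None else f"row-{n}"
        for n, img in enumerate(images)
    )
    return VoxelMatrix(
        data=np.vstack(rows),
        voxel_index=idx,
        roi_label=int(roi_label),
        side=side,
        subject_ids=subject_ids,
    )


def sort_sides(
    left_image: ParametricImage,
    right_image: ParametricImage,
    worse_body_side: str,
) -> tuple[ParametricImage, ParametricImage]:
    """Relabel hemisphere images as (better, worse) from the worse *body* side.

    The brain hemisphere contralateral to the worse body side is the worse
    hemisphere: worse body side "left" makes the right hemisphere image worse.
    """
    if worse_body_side not in ("left", "right"):
        raise ValidationError(
            f"worse_body_side must be 'left' or 'right', got {worse_body_side!r}"
        )
    worse_hemisphere = "right" if worse_body_side == "left" else "left"
    by_side = {"left": left_image, "right": right_image}
    worse = replace(by_side[worse_hemisphere], side="worse")
    better = replace(
        by_side["right" if worse_hemisphere == "left" else "left"], side="better"
    )
    return better, worse
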