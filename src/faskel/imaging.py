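"""Volume containers, tensor-derived scalar maps, masks and feature matrices.

The analyses in this package operate on skeletonized fractional-anisotropy
(FA) images: 3D volumes that are zero everywhere except on a thin
white-matter skeleton. This module provides the voxel-image container
(NIfTI-1 backed), the standard diffusion-tensor scalar maps (FA, axial and
radial diffusivity from the tensor eigenvalues), skeleton/common-mask
construction, and the bijection between masked voxel images and the
subjects-by-voxels feature matrices consumed by the multivariate analyses.

Voxel ordering is fixed: mask voxels are enumerated in C (row-major) ravel
order of the 3D grid, so feature columns are stable across calls and
documented. Voxel coordinates are 0-based array indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger("faskel")

__all__ = [
    "VoxelImage",
    "CommonMask",
    "FeatureMatrix",
    "fa_from_eigenvalues",
    "axial_radial",
    "skeleton_mask",
    "compute_common_mask",
    "vectorize",
    "devectorize",
]


@dataclass
class VoxelImage:
    """A 3D scalar volume with a voxel-to-world affine.

    Carrier for FA maps, SVM weight maps and statistic maps alike; the
    interpretation of ``data`` is up to the producing operation.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("voxel data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path) -> "VoxelImage":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj).astype(float), img.affine)


@dataclass
class CommonMask:
    """Binary voxel mask shared by all subjects."""

    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def indices(self) -> np.ndarray:
        """Flat C-order indices of the mask voxels (the fixed voxel ordering)."""
        return np.flatnonzero(self.mask.ravel(order="C"))

    def coordinates(self) -> np.ndarray:
        """(n_voxels, 3) array of 0-based voxel coordinates, in mask order."""
        return np.column_stack(np.unravel_index(self.indices, self.mask.shape))

    def to_image(self) -> VoxelImage:
        return VoxelImage(self.mask.astype(float), self.affine)


@dataclass
class FeatureMatrix:
    """Subjects-by-voxels matrix tied to the mask that defined its columns."""

    values: np.ndarray
    subject_ids: list[str]
    mask: CommonMask

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2D (subjects x voxels)")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("row count must equal number of subject ids")
        if self.values.shape[1] != self.mask.n_voxels:
            raise ValueError(
                f"column count {self.values.shape[1]} != mask voxels {self.mask.n_voxels}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        cols = [f"vox_{i}" for i in range(self.n_voxels)]
        return pd.DataFrame(self.values, index=self.subject_ids, columns=cols)


def _prepare_eigenvalues(l1, l2, l3) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Broadcast, clamp negatives to zero and sort descending.

    Negative eigenvalues occur in noisy tensor fits; they are clamped with a
    warning. Unsorted inputs are sorted descending with a warning so that
    axial diffusivity is always the largest eigenvalue.
    """
    arrs = np.broadcast_arrays(
        np.asarray(l1, dtype=float), np.asarray(l2, dtype=float), np.asarray(l3, dtype=float)
    )
    stacked = np.stack(arrs, axis=-1)
    if np.any(stacked < 0):
        logger.warning("negative eigenvalues clamped to 0")
        stacked = np.clip(stacked, 0.0, None)
    srt = np.sort(stacked, axis=-1)[..., ::-1]
    if not np.allclose(srt, stacked):
        logger.warning("eigenvalues were not sorted descending; sorted internally")
    return srt[..., 0], srt[..., 1], srt[..., 2]


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy from the diffusion-tensor eigenvalues.

    FA = sqrt(1/2) * sqrt((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2) / sqrt(l1^2+l2^2+l3^2),
    the normalized standard deviation of the eigenvalues: 0 for isotropic
    diffusion, 1 for a degenerate "stick" tensor. Scale-invariant. Voxels with
    all-zero eigenvalues are assigned FA = 0 by convention (logged).
    """
    a, b, c = _prepare_eigenvalues(l1, l2, l3)
    norm_sq = a * a + b * b + c * c
    zero = norm_sq == 0
    if np.any(zero):
        logger.info("all-zero eigenvalue voxels assigned FA = 0")
    num = (a - b) ** 2 + (b - c) ** 2 + (c - a) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(num / np.where(zero, 1.0, norm_sq))
    fa = np.where(zero, 0.0, np.clip(fa, 0.0, 1.0))
    return fa if fa.ndim else float(fa)


def axial_radial(l1, l2, l3):
    """Axial (= largest eigenvalue) and radial (= mean of the two smaller)
    diffusivity, in the eigenvalues' units (typically mm^2/s)."""
    a, b, c = _prepare_eigenvalues(l1, l2, l3)
    ad = a
    rd = (b + c) / 2.0
    if ad.ndim == 0:
        return float(ad), float(rd)
    return ad, rd


def skeleton_mask(mean_fa: VoxelImage, threshold: float = 0.2) -> CommonMask:
    """Threshold a mean-FA image into a skeleton mask.

    The comparison is strict (FA > threshold): boundary voxels at exactly the
    threshold are excluded, matching common TBSS practice at the 0.2 cutoff.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    mask = mean_fa.data > threshold
    if not mask.any():
        raise ValueError(f"no voxels exceed FA threshold {threshold}")
    return CommonMask(mask, mean_fa.affine)


def compute_common_mask(images: Sequence[VoxelImage]) -> CommonMask:
    """Voxels present (nonzero and finite) in every subject's image.

    Mirrors the exclusion of voxels missing in any subject before the
    multivariate analyses; order of the input list is irrelevant.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    shape = images[0].shape
    mask = np.ones(shape, dtype=bool)
    for img in images:
        if img.shape != shape:
            raise ValueError(f"shape mismatch: {img.shape} vs {shape}")
        mask &= (img.data != 0) & np.isfinite(img.data)
    if not mask.any():
        raise ValueError("common mask is empty")
    logger.info("common mask: %d voxels", int(mask.sum()))
    return CommonMask(mask, images[0].affine)


def vectorize(
    images: Sequence[VoxelImage],
    mask: CommonMask,
    subject_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Stack each image's mask-voxel values into one row per subject.

    Columns follow the mask's fixed C-order voxel enumeration, so the
    column -> voxel-coordinate mapping is stable and invertible.
    """
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(len(images))]
    if len(subject_ids) != len(images):
        raise ValueError("one subject id per image required")
    idx = mask.indices
    rows = np.empty((len(images), idx.size), dtype=float)
    for i, img in enumerate(images):
        if img.shape != mask.mask.shape:
            raise ValueError("image shape does not match mask shape")
        rows[i] = img.data.ravel(order="C")[idx]
    return FeatureMatrix(rows, list(subject_ids), mask)


def devectorize(vector: np.ndarray, mask: CommonMask) -> VoxelImage:
    """Scatter a voxel vector back onto the 3D grid (zero off the mask)."""
    vector = np.asarray(vector, dtype=float).ravel()
    if vector.size != mask.n_voxels:
        raise ValueError(f"vector length {vector.size} != mask voxels {mask.n_voxels}")
    flat = np.zeros(mask.mask.size, dtype=float)
    flat[mask.indices] = vector
    return VoxelImage(flat.reshape(mask.mask.shape), mask.affine)
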