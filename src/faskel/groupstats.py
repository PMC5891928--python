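"""Voxelwise two-group inference on the skeleton with TFCE and FWE control.

The group comparison is a pooled-variance two-sample t statistic per
skeleton voxel, oriented one-sidedly (the patients<controls direction tests
for FA reductions in patients). Threshold-free cluster enhancement (TFCE)
integrates cluster extent and height across all thresholds,

    TFCE(v) = sum_h  e_v(h)^E * h^H * dh,

where e_v(h) is the extent of the connected component containing voxel v in
the supra-threshold set {t >= h}; defaults E = 0.5, H = 2, 26-connectivity
and dh = max(t)/100 follow common randomise practice. Family-wise error is
controlled by the permutation distribution of the image-wide maximum
enhanced statistic: corrected p per voxel is
(#{null maxima >= observed} + 1) / (n_perm + 1), the convention that counts
the observed labeling itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import CommonMask, FeatureMatrix, VoxelImage

logger = logging.getLogger("faskel")

__all__ = [
    "StatImage",
    "TFCEConfig",
    "TFCEResult",
    "voxelwise_tstat",
    "tfce_enhance",
    "fwe_maxstat",
    "extract_clusters",
]

DIRECTIONS = ("patients<controls", "patients>controls")


@dataclass
class StatImage:
    """Per-voxel statistic on a mask, zero elsewhere."""

    data: np.ndarray
    df: int
    direction: str
    mask: CommonMask | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("statistic image must be finite")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")


@dataclass
class TFCEConfig:
    """TFCE exponents, integration step and neighbourhood.

    ``dh=None`` resolves to max(statistic)/100 at enhancement time.
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def _tstat_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column, zero where variance vanishes."""
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    ss = ((a - m1) ** 2).sum(axis=0) + ((b - m2) ** 2).sum(axis=0)
    sp2 = ss / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero = se == 0
    if np.any(zero):
        logger.warning("%d voxels have zero pooled variance; t set to 0", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.where(zero, 1.0, se)
    return np.where(zero, 0.0, t)


def voxelwise_tstat(
    patients: FeatureMatrix,
    controls: FeatureMatrix,
    direction: str = "patients<controls",
) -> StatImage:
    """Two-sample pooled t per mask voxel, oriented so positive values
    support the requested direction."""
    if patients.n_voxels != controls.n_voxels:
        raise ValueError("patient and control matrices cover different masks")
    if patients.n_subjects < 2 or controls.n_subjects < 2:
        raise ValueError("need at least 2 subjects per group")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    t = _tstat_rows(patients.values, controls.values)
    if direction == "patients<controls":
        t = -t
    mask = patients.mask
    flat = np.zeros(mask.mask.size)
    flat[mask.indices] = t
    return StatImage(
        data=flat.reshape(mask.mask.shape),
        df=patients.n_subjects + controls.n_subjects - 2,
        direction=direction,
        mask=mask,
    )


def tfce_enhance(stat: StatImage | np.ndarray, config: TFCEConfig | None = None) -> VoxelImage:
    """Threshold-free cluster enhancement of a one-sided statistic image.

    Negative statistic values contribute nothing (clamped to 0). The sum
    runs over thresholds h = dh, 2 dh, ... up to the image maximum; at each
    h, every supra-threshold voxel accumulates extent^E * h^H * dh, with
    extent the size of its connected component at that height.
    """
    config = config or TFCEConfig()
    data = stat.data if isinstance(stat, StatImage) else np.asarray(stat, dtype=float)
    pos = np.clip(data, 0.0, None)
    hmax = float(pos.max())
    if hmax == 0.0:
        return VoxelImage(np.zeros_like(pos))
    dh = config.dh if config.dh is not None else hmax / 100.0
    if dh >= hmax:
        raise ValueError(f"dh = {dh:g} leaves no integration step below max {hmax:g}")
    structure = _structure(config.connectivity)
    enhanced = np.zeros_like(pos)
    n_steps = int(np.floor(hmax / dh + 1e-9))
    tol = 1e-12 * hmax  # final step k*dh can exceed hmax by an ulp
    for k in range(1, n_steps + 1):
        h = k * dh
        supra = pos >= h - tol
        labels, n_comp = ndimage.label(supra, structure=structure)
        if n_comp == 0:
            break
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        enhanced += np.where(supra, sizes[labels] ** config.E * h**config.H * dh, 0.0)
    return VoxelImage(enhanced)


@dataclass
class TFCEResult:
    """Observed enhancement, its max-statistic null and corrected p-values."""

    enhanced: VoxelImage
    max_null: np.ndarray
    p_fwe: VoxelImage
    clusters: pd.DataFrame
    stat: StatImage
    alpha: float
    seed: int


def fwe_maxstat(
    patients: FeatureMatrix,
    controls: FeatureMatrix,
    tfce_config: TFCEConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    direction: str = "patients<controls",
) -> TFCEResult:
    """Permutation FWE correction of the TFCE map by the maximum statistic.

    Group labels are permuted over the pooled subjects (group sizes
    preserved); each permutation records the image-wide maximum of the
    enhanced statistic. Per-voxel corrected p is
    (#{null maxima >= observed} + 1)/(n_perm + 1); off-mask voxels carry
    p = 1. Clusters are the connected components of {p_fwe < alpha}.
    """
    tfce_config = tfce_config or TFCEConfig()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if patients.n_subjects < 2 or controls.n_subjects < 2:
        raise ValueError("need at least 2 subjects per group")
    mask = patients.mask
    observed_stat = voxelwise_tstat(patients, controls, direction)
    observed_enh = tfce_enhance(observed_stat, tfce_config)
    pooled = np.vstack([patients.values, controls.values])
    n1 = patients.n_subjects
    n = pooled.shape[0]
    sign = -1.0 if direction == "patients<controls" else 1.0
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    cfg = tfce_config
    for k in range(n_perm):
        idx = rng.permutation(n)
        t = sign * _tstat_rows(pooled[idx[:n1]], pooled[idx[n1:]])
        flat = np.zeros(mask.mask.size)
        flat[mask.indices] = t
        vol = flat.reshape(mask.mask.shape)
        vmax = float(np.clip(vol, 0, None).max())
        if vmax == 0.0:
            max_null[k] = 0.0
            continue
        if cfg.dh is not None and cfg.dh >= vmax:
            # an explicit step larger than this permutation's maximum leaves
            # no integration steps: the enhanced image is identically zero
            max_null[k] = 0.0
            continue
        enh = tfce_enhance(vol, cfg)
        max_null[k] = float(enh.data.max())
    exceed = (max_null[None, :] >= observed_enh.data.ravel()[mask.indices][:, None]).sum(axis=1)
    p_vec = (exceed + 1) / (n_perm + 1)
    p_flat = np.ones(mask.mask.size)
    p_flat[mask.indices] = p_vec
    p_img = VoxelImage(p_flat.reshape(mask.mask.shape))
    clusters = extract_clusters(p_img, alpha, tfce_config.connectivity)
    return TFCEResult(
        enhanced=observed_enh,
        max_null=max_null,
        p_fwe=p_img,
        clusters=clusters,
        stat=observed_stat,
        alpha=alpha,
        seed=seed,
    )


def extract_clusters(
    p_fwe: VoxelImage, alpha: float = 0.05, connectivity: int = 26
) -> pd.DataFrame:
    """Connected components of {p_fwe < alpha}: size, peak voxel, peak p.

    Peak coordinates are 0-based voxel indices of this grid; the peak is the
    minimum corrected p within the cluster (first in C order on ties).
    """
    sig = p_fwe.data < alpha
    labels, n_comp = ndimage.label(sig, structure=_structure(connectivity))
    rows = []
    for comp in range(1, n_comp + 1):
        coords = np.argwhere(labels == comp)
        pvals = p_fwe.data[tuple(coords.T)]
        peak = coords[int(np.argmin(pvals))]
        rows.append(
            dict(
                cluster=comp,
                size_voxels=int(len(coords)),
                peak_x=int(peak[0]),
                peak_y=int(peak[1]),
                peak_z=int(peak[2]),
                peak_p_fwe=float(pvals.min()),
            )
        )
    df = pd.DataFrame(rows, columns=["cluster", "size_voxels", "peak_x", "peak_y", "peak_z", "peak_p_fwe"])
    return df.sort_values("size_voxels", ascending=False).reset_index(drop=True) if rows else df
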