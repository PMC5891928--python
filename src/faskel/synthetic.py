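"""Synthetic matched cohorts of skeletonized FA images with known ground truth.

No diffusion MRI data accompany the study design this package implements, so
every downstream stage is exercised on simulated cohorts that reproduce the
*structure* of skeletonized FA data: a thin, connected white-matter-like
skeleton with baseline FA above the 0.2 threshold, age/sex-matched
patient-control pairs, a spatially contiguous FA reduction in patients, and
clinical scores (PANSS subscales, chlorpromazine-equivalent dose) whose
association with the image pattern is controlled by a coupling parameter.

The generator is deterministic given a seed, and the ground-truth effect
mask is carried alongside the cohort so that recovery can be scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import CommonMask, VoxelImage

logger = logging.getLogger("faskel")

__all__ = [
    "SkeletonTemplate",
    "CohortSpec",
    "SubjectRecord",
    "MatchedPair",
    "Cohort",
    "generate_skeleton_template",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

# Published cohort descriptives used as sampling anchors for clinical scores:
# PANSS subscale means/SDs and the chlorpromazine-equivalent median.
PANSS_POS = (13.9, 4.9, 7.0, 49.0)  # mean, sd, floor, ceiling
PANSS_NEG = (15.7, 6.1, 7.0, 49.0)
PANSS_GEN = (32.8, 8.5, 16.0, 112.0)
CPZ_MEDIAN = 337.0
CPZ_LOG_SD = 0.6


@dataclass
class SkeletonTemplate:
    """A thinned, connected stand-in for a white-matter FA skeleton.

    ``baseline`` holds the noise-free mean FA per voxel: strictly above the
    0.2 skeleton threshold on the mask, zero elsewhere.
    """

    mask: np.ndarray
    baseline: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if not self.mask.any():
            raise ValueError("skeleton mask is empty")
        if self.mask.shape != self.baseline.shape:
            raise ValueError("mask and baseline shapes differ")
        if np.any(self.baseline[self.mask] <= 0.2):
            raise ValueError("baseline FA must exceed 0.2 on the skeleton")
        if np.any(self.baseline[~self.mask] != 0):
            raise ValueError("baseline must be zero off the skeleton")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def common_mask(self) -> CommonMask:
        return CommonMask(self.mask.copy())


@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults mirror the matched two-group design this package targets:
    77 patient-control pairs, a contiguous FA reduction of 0.05 covering 20%
    of the skeleton, per-voxel Gaussian noise of SD 0.02, and no built-in
    association between images and clinical scores. ``severity_sd`` scales
    per-patient variability of the effect amplitude (disease severity);
    without it no regression could recover image-coupled clinical scores.
    """

    n_pairs: int = 77
    effect_fraction: float = 0.2
    effect_delta: float = 0.05
    noise_sd: float = 0.02
    clinical_coupling: float = 0.0
    severity_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if not (0.0 <= self.effect_fraction <= 1.0):
            raise ValueError("effect_fraction must lie in [0, 1]")
        if self.effect_delta < 0:
            raise ValueError("effect_delta must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.clinical_coupling <= 1.0):
            raise ValueError("clinical_coupling must lie in [0, 1]")
        if self.severity_sd < 0:
            raise ValueError("severity_sd must be >= 0")


@dataclass
class SubjectRecord:
    subject_id: str
    image: VoxelImage
    label: str  # 'patient' or 'control'
    age: float
    sex: str  # 'F' or 'M'
    panss_pos: float = float("nan")
    panss_neg: float = float("nan")
    panss_gen: float = float("nan")
    panss_total: float = float("nan")
    cpz: float = float("nan")

    def __post_init__(self) -> None:
        if self.label not in ("patient", "control"):
            raise ValueError("label must be 'patient' or 'control'")
        if self.label == "control" and np.isfinite(self.cpz):
            raise ValueError("controls cannot carry a chlorpromazine dose")


@dataclass
class MatchedPair:
    pair_id: int
    patient: SubjectRecord
    control: SubjectRecord

    def __post_init__(self) -> None:
        if self.patient.label != "patient" or self.control.label != "control":
            raise ValueError("a matched pair is one patient plus one control")
        if self.patient.age != self.control.age or self.patient.sex != self.control.sex:
            raise ValueError("pair members must share age and sex")


@dataclass
class Cohort:
    pairs: list[MatchedPair]
    effect_mask: np.ndarray
    template: SkeletonTemplate

    def __post_init__(self) -> None:
        self.effect_mask = np.asarray(self.effect_mask, dtype=bool)
        if np.any(self.effect_mask & ~self.template.mask):
            raise ValueError("effect mask must be contained in the skeleton")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def subjects(self) -> list[SubjectRecord]:
        out: list[SubjectRecord] = []
        for p in self.pairs:
            out.extend([p.patient, p.control])
        return out

    @property
    def patients(self) -> list[SubjectRecord]:
        return [p.patient for p in self.pairs]

    @property
    def controls(self) -> list[SubjectRecord]:
        return [p.control for p in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            for s in (p.patient, p.control):
                rows.append(
                    dict(
                        subject_id=s.subject_id,
                        pair_id=p.pair_id,
                        label=s.label,
                        age=s.age,
                        sex=s.sex,
                        panss_pos=s.panss_pos,
                        panss_neg=s.panss_neg,
                        panss_gen=s.panss_gen,
                        panss_total=s.panss_total,
                        cpz=s.cpz,
                    )
                )
        return pd.DataFrame(rows)


_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=int
)


def generate_skeleton_template(
    shape: tuple[int, int, int] = (20, 20, 20),
    fill_fraction: float = 0.1,
    seed: int = 0,
) -> SkeletonTemplate:
    """Grow a connected, thinned skeleton covering ~fill_fraction of the grid.

    A branching self-avoiding random walk from the grid centre emulates the
    curvilinear, width-one geometry of a tract skeleton without modelling
    anatomy. Baseline FA per skeleton voxel is uniform on [0.25, 0.8], safely
    above the 0.2 threshold.
    """
    shape = tuple(int(d) for d in shape)
    if len(shape) != 3 or any(d < 3 for d in shape):
        raise ValueError("shape must have 3 dimensions, each >= 3")
    if not (0.0 < fill_fraction < 1.0):
        raise ValueError("fill_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    target = max(2, int(round(fill_fraction * np.prod(shape))))
    mask = np.zeros(shape, dtype=bool)
    pos = np.array([d // 2 for d in shape], dtype=int)
    mask[tuple(pos)] = True
    heads = [pos]
    occupied = [pos]
    lo = np.zeros(3, dtype=int)
    hi = np.array(shape, dtype=int) - 1
    while int(mask.sum()) < target:
        head = heads[rng.integers(len(heads))]
        for _ in range(8):  # try a few directions before abandoning the head
            step = _STEPS[rng.integers(6)]
            nxt = np.clip(head + step, lo, hi)
            if not mask[tuple(nxt)]:
                mask[tuple(nxt)] = True
                occupied.append(nxt)
                heads.append(nxt)
                if rng.random() < 0.03:  # occasional branch from an old voxel
                    heads.append(occupied[rng.integers(len(occupied))])
                if len(heads) > 32:
                    heads = heads[-32:]
                break
        else:
            # head boxed in: restart from a random occupied voxel
            heads.append(occupied[rng.integers(len(occupied))])
    baseline = np.zeros(shape, dtype=float)
    baseline[mask] = rng.uniform(0.25, 0.8, size=int(mask.sum()))
    return SkeletonTemplate(mask, baseline)


def _effect_mask(template: SkeletonTemplate, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Union of random spherical blobs intersected with the skeleton,
    trimmed to cover the requested fraction of skeleton voxels exactly."""
    n_target = int(round(fraction * template.n_voxels))
    mask = np.zeros(template.shape, dtype=bool)
    if n_target == 0:
        return mask
    skel_coords = np.argwhere(template.mask)
    grid = np.argwhere(np.ones(template.shape, dtype=bool)).reshape(*template.shape, 3)
    while int(mask.sum()) < n_target:
        centre = skel_coords[rng.integers(len(skel_coords))]
        radius = rng.uniform(2.0, 5.0)
        dist2 = ((grid - centre) ** 2).sum(axis=-1)
        blob = (dist2 <= radius**2) & template.mask & ~mask
        overshoot = int(mask.sum()) + int(blob.sum()) - n_target
        if overshoot > 0:
            # drop the blob voxels farthest from the centre to land exactly
            coords = np.argwhere(blob)
            order = np.argsort(dist2[tuple(coords.T)])[::-1]
            for c in coords[order[:overshoot]]:
                blob[tuple(c)] = False
        mask |= blob
    return mask


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, z: float) -> float:
    """One truncated-normal draw whose standard-normal innovation is ``z``."""
    return float(np.clip(mean + sd * z, lo, hi))


def generate_cohort(template: SkeletonTemplate, spec: CohortSpec) -> Cohort:
    """Sample a matched cohort from the template under the given conditions.

    Patient images are baseline minus a per-subject severity-scaled
    ``effect_delta`` inside a contiguous effect region plus i.i.d. Gaussian
    noise; control images are baseline plus noise; all voxel values are
    clipped to [0, 1]. Each pair shares age
    and sex. PANSS subscales and chlorpromazine dose are sampled around the
    published cohort descriptives; ``clinical_coupling`` linearly loads the
    scores on the patient's mean FA inside the effect region (lower FA,
    higher severity). One patient's dose is flagged missing to exercise
    missing-data handling.
    """
    rng = np.random.default_rng(spec.seed)
    effect = _effect_mask(template, spec.effect_fraction, rng)
    skel = template.mask
    n_vox = template.n_voxels
    base = template.baseline[skel]
    eff_on_skel = effect[skel]

    def make_image(is_patient: bool) -> VoxelImage:
        vals = base.copy()
        if is_patient:
            # patients differ in how pronounced the FA reduction is:
            # per-subject severity scales the effect amplitude around 1
            scale = max(0.0, 1.0 + spec.severity_sd * rng.standard_normal())
            vals = vals - spec.effect_delta * scale * eff_on_skel
        vals = vals + rng.normal(0.0, spec.noise_sd, size=n_vox)
        n_clip = int(np.sum(vals <= 0.0))
        if n_clip > 0.01 * n_vox:
            logger.warning(
                "effect_delta/noise clip %d of %d skeleton voxels to 0", n_clip, n_vox
            )
        vol = np.zeros(template.shape, dtype=float)
        vol[skel] = np.clip(vals, 0.0, 1.0)
        return VoxelImage(vol)

    patients_img = [make_image(True) for _ in range(spec.n_pairs)]
    controls_img = [make_image(False) for _ in range(spec.n_pairs)]
    ages = rng.integers(18, 46, size=spec.n_pairs).astype(float)
    sexes = rng.choice(["F", "M"], size=spec.n_pairs)

    # clinical coupling: standardized negative mean FA in the effect region
    if effect.any():
        sev = np.array([-img.data[effect].mean() for img in patients_img])
    else:
        sev = np.array([-img.data[skel].mean() for img in patients_img])
    sd = sev.std()
    z_img = (sev - sev.mean()) / sd if sd > 0 else np.zeros(spec.n_pairs)
    c = spec.clinical_coupling
    mix = np.sqrt(max(0.0, 1.0 - c * c))
    missing_cpz = int(rng.integers(spec.n_pairs))

    pairs: list[MatchedPair] = []
    for i in range(spec.n_pairs):
        def innovation() -> float:
            return c * z_img[i] + mix * rng.standard_normal()

        pos = _truncnorm(rng, *PANSS_POS[:2], *PANSS_POS[2:], innovation())
        neg = _truncnorm(rng, *PANSS_NEG[:2], *PANSS_NEG[2:], innovation())
        gen = _truncnorm(rng, *PANSS_GEN[:2], *PANSS_GEN[2:], innovation())
        cpz = float(CPZ_MEDIAN * np.exp(CPZ_LOG_SD * innovation()))
        if i == missing_cpz:
            cpz = float("nan")
        patient = SubjectRecord(
            subject_id=f"P{i:03d}",
            image=patients_img[i],
            label="patient",
            age=float(ages[i]),
            sex=str(sexes[i]),
            panss_pos=pos,
            panss_neg=neg,
            panss_gen=gen,
            panss_total=pos + neg + gen,
            cpz=cpz,
        )
        control = SubjectRecord(
            subject_id=f"C{i:03d}",
            image=controls_img[i],
            label="control",
            age=float(ages[i]),
            sex=str(sexes[i]),
        )
        pairs.append(MatchedPair(pair_id=i, patient=patient, control=control))
    return Cohort(pairs=pairs, effect_mask=effect, template=template)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Persist a cohort: one NIfTI volume per subject, the cohort table as
    CSV, the skeleton baseline/mask and the ground-truth effect mask."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        s.image.save(outdir / f"{s.subject_id}.nii.gz")
    cohort.to_frame().to_csv(outdir / "cohort.csv", index=False)
    VoxelImage(cohort.template.baseline).save(outdir / "skeleton_baseline.nii.gz")
    VoxelImage(cohort.effect_mask.astype(float)).save(outdir / "effect_mask.nii.gz")


def read_cohort(indir) -> Cohort:
    """Inverse of :func:`write_cohort`."""
    indir = Path(indir)
    table = pd.read_csv(indir / "cohort.csv")
    baseline = VoxelImage.load(indir / "skeleton_baseline.nii.gz")
    template = SkeletonTemplate(baseline.data > 0, baseline.data)
    effect = VoxelImage.load(indir / "effect_mask.nii.gz").data > 0.5
    pairs: list[MatchedPair] = []
    for pair_id, grp in table.groupby("pair_id"):
        members = {}
        for _, row in grp.iterrows():
            members[row["label"]] = SubjectRecord(
                subject_id=row["subject_id"],
                image=VoxelImage.load(indir / f"{row['subject_id']}.nii.gz"),
                label=row["label"],
                age=float(row["age"]),
                sex=str(row["sex"]),
                panss_pos=float(row["panss_pos"]),
                panss_neg=float(row["panss_neg"]),
                panss_gen=float(row["panss_gen"]),
                panss_total=float(row["panss_total"]),
                cpz=float(row["cpz"]),
            )
        pairs.append(MatchedPair(int(pair_id), members["patient"], members["control"]))
    return Cohort(pairs=pairs, effect_mask=effect, template=template)
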