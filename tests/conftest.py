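import numpy as np
import pytest

from faskel import CohortSpec, generate_cohort, generate_skeleton_template
from faskel.imaging import compute_common_mask, vectorize


@pytest.fixture(scope="session")
def small_template():
    """~90-voxel skeleton on a 12^3 grid; fast enough for repeated CV."""
    return generate_skeleton_template(shape=(12, 12, 12), fill_fraction=0.05, seed=3)


@pytest.fixture(scope="session")
def medium_template():
    """~800-voxel skeleton on a 20^3 grid, the scale of the recovery sims."""
    return generate_skeleton_template(shape=(20, 20, 20), fill_fraction=0.1, seed=3)


@pytest.fixture(scope="session")
def effect_cohort(medium_template):
    """Signal-recovery conditions: 40 pairs, 20% effect coverage, FA drop
    0.05, noise SD 0.02."""
    spec = CohortSpec(
        n_pairs=40, effect_fraction=0.2, effect_delta=0.05, noise_sd=0.02, seed=7
    )
    return generate_cohort(medium_template, spec)


@pytest.fixture(scope="session")
def null_cohort(small_template):
    """No group effect, no clinical coupling."""
    spec = CohortSpec(
        n_pairs=10, effect_fraction=0.2, effect_delta=0.0, noise_sd=0.02,
        clinical_coupling=0.0, seed=11,
    )
    return generate_cohort(small_template, spec)


def cohort_features(cohort):
    """(patients FeatureMatrix, controls FeatureMatrix) over the common mask."""
    subjects = cohort.subjects
    mask = compute_common_mask([s.image for s in subjects])
    pat = vectorize(
        [s.image for s in cohort.patients], mask, [s.subject_id for s in cohort.patients]
    )
    con = vectorize(
        [s.image for s in cohort.controls], mask, [s.subject_id for s in cohort.controls]
    )
    return pat, con


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
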