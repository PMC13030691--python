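import numpy as np
import pandas as pd
import pytest

from petrepeat import CohortParams, LabeledImage


@pytest.fixture
def small_params():
    """A small, fast synthetic cohort."""
    return CohortParams(n_patients=4, lesions_per_patient_mean=5, seed=11)


@pytest.fixture
def big_cohort_pairs():
    """~5000-lesion cohort with known noise structure (tau=0.05, sigma_w=0.1)."""
    from petrepeat import generate_paired_features

    params = CohortParams(
        n_patients=250,
        lesions_per_patient_mean=20,
        patient_bias_sd=0.05,
        lesion_noise_sd=0.1,
        seed=7,
    )
    pairs, truth = generate_paired_features(params)
    return params, pairs, truth


def random_labeled_image(rng: np.random.Generator, shape=(16, 16, 16), n_rois=3) -> LabeledImage:
    """Random SUV grid with a few random blob ROIs (possibly ragged shapes)."""
    suv = rng.gamma(2.0, 1.5, shape)
    labels = np.zeros(shape, dtype=np.int32)
    for lid in range(1, n_rois + 1):
        n_vox = rng.integers(1, 40)
        flat = rng.choice(np.prod(shape), size=n_vox, replace=False)
        idx = np.unravel_index(flat, shape)
        labels[idx] = lid  # later labels may overwrite earlier ones: still disjoint
    voxel = tuple(rng.uniform(1.0, 5.0, 3))
    return LabeledImage(suv=suv, labels=labels, voxel_size_mm=voxel, patient_id="PX", timepoint="test")


def make_pairs(records) -> pd.DataFrame:
    """Build a wide pair table from (patient, lesion, feature_dict_test, feature_dict_retest)
    or from per-feature scalar pairs applied to all four features."""
    rows = []
    for patient, lesion, test_val, retest_val in records:
        row = {"patient_id": patient, "lesion_id": lesion}
        for f in ("suv_max", "suv_mean", "suv_total", "volume_cc"):
            row[f"{f}_test"] = test_val
            row[f"{f}_retest"] = retest_val
        rows.append(row)
    return pd.DataFrame(rows)
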