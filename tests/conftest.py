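import numpy as np
import pandas as pd
import pytest

from morphrisk.synthetic_cohort import (
    default_study_config,
    make_template,
    sample_cohort,
)
from morphrisk.study_pipeline import build_feature_table


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def study_cohort():
    """One default-sized cohort (n=203, exact composition), shared across tests."""
    faces, cohort, truth = sample_cohort(default_study_config(seed=0))
    return faces, cohort, truth


@pytest.fixture(scope="session")
def study_features(study_cohort):
    faces, cohort, _ = study_cohort
    return build_feature_table(faces), cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort_frame(n=6, **overrides):
    """Minimal valid cohort DataFrame for I/O and validation tests."""
    base = pd.DataFrame(
        {
            "subject_id": [f"T{i:03d}" for i in range(n)],
            "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
            "group": ["NSR", "SR"] * (n // 2) + ["NSR"] * (n % 2),
            "age": [25] * n,
            "bmi": [22.5] * n,
            "diagnosis": ["single_episode"] * n,
            "psychotic": [False] * n,
            "ims": [0] * n,
            "phq9": [15] * n,
            "gad7": [10] * n,
            "hdrs17": [20] * n,
            "hama": [18] * n,
            "ymrs": [2] * n,
        }
    )
    for col, vals in overrides.items():
        base[col] = vals
    return base
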