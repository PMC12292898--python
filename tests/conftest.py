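import math

import numpy as np
import pytest

from gaitscore.synthetic import (
    MisalignmentTruth,
    generate_cohort,
    generate_subject,
)


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free, perfectly mounted level-0 subject (one trial)."""
    trials, truth = generate_subject(0, seed=7, noise=False, n_trials=1)
    return trials[0], truth


@pytest.fixture(scope="session")
def misaligned_subject():
    """Noise-free subject with (pitch, yaw, roll) = (10°, 5°, 8°) on the left
    IMU and a different triple on the right."""
    mis = {
        "left": MisalignmentTruth(math.radians(10), math.radians(5),
                                  math.radians(8)),
        "right": MisalignmentTruth(math.radians(-7), math.radians(3),
                                   math.radians(-12)),
    }
    trials, truth = generate_subject(0, seed=42, misalignment=mis,
                                     noise=False, n_trials=1)
    return trials[0], truth


@pytest.fixture(scope="session")
def small_cohort():
    """4 HC / 2 PD-1 / 2 PD-2 cohort (24 trials) with default noise."""
    cohort, rows = generate_cohort(n_hc=4, n_pd1=2, n_pd2=2, seed=5)
    return cohort, rows


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    from gaitscore.pipeline import extract_cohort_features

    cohort, _rows = small_cohort
    subjects = [trials for trials, _ in cohort]
    labels = [truth.subject.updrs_level for _, truth in cohort]
    feats = extract_cohort_features(subjects, seed=5)
    return feats, labels
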