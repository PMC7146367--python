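import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from emgconfounds import (
    ClassifierSpec,
    GeneratorConfig,
    extract_set,
    generate_dataset,
    segment,
)


@pytest.fixture(scope="session")
def tiny_config():
    """Small but structurally complete position dataset: 2 subjects,
    3 positions, 4 motions, 3 reps."""
    return GeneratorConfig(
        n_subjects=2,
        n_channels=4,
        motion_classes=("no_motion", "power_grip", "wrist_flexion", "hand_open"),
        condition_kind="position",
        conditions=(0, 1, 2),
        reps_per_condition=3,
        trial_duration=0.6,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_windows(tiny_dataset):
    return segment(tiny_dataset, window_ms=150, increment_ms=50)


@pytest.fixture(scope="session")
def tiny_td(tiny_windows):
    return extract_set(tiny_windows, "TD")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def lda_spec():
    return ClassifierSpec("lda")
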