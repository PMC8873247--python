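"""Shared fixtures: trained detector banks and synthetic recordings.

Thread pools are pinned to one thread so that network training produces
bit-identical results regardless of the host's core count.
"""

import numpy as np
import pytest
from hypothesis import settings
from threadpoolctl import threadpool_limits

from ppgnorm import detector as det
from ppgnorm import synthetic as syn

_limits = threadpool_limits(limits=1)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_cohort():
    """Artifact-free training cohort: 9 subjects x 2 sessions, 40 s each."""
    return syn.generate_cohort(
        n_subjects=(5, 4), sessions_per_subject=2, duration=40.0, seed=0
    )


@pytest.fixture(scope="session")
def clean_bank(clean_cohort):
    """Six detectors trained on ~6000 clean labeled windows (fixed seed)."""
    X, targets = det.make_training_set(
        clean_cohort.recordings.values(), max_windows=6000, seed=0
    )
    return det.train_detectors(X, targets, det.TrainingConfig(seed=0))


@pytest.fixture(scope="session")
def mixed_bank():
    """Detectors trained on a cohort that includes artifacts and dropouts."""
    cohort = syn.generate_cohort(
        n_subjects=(3, 3), sessions_per_subject=2, duration=40.0, seed=9,
        artifact_spec=(0.12, 0.12),
    )
    X, targets = det.make_training_set(cohort.recordings.values(), max_windows=6000, seed=0)
    return det.train_detectors(X, targets, det.TrainingConfig(seed=0))


@pytest.fixture(scope="session")
def clean_recording():
    """One clean 40 s recording with ground truth (group-1 archetype)."""
    profile = syn.draw_subject_profile("group1", np.random.default_rng(5))
    return syn.generate_recording(profile, 40.0, seed=50, subject_id="s01", session_id="ref1")
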