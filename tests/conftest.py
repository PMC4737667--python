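"""Shared fixtures: small synthetic datasets sized for fast unit tests."""

import numpy as np
import pytest

from sparsenets import (
    BrainMask,
    SyntheticSpec,
    generate_mask,
    generate_subject,
    generate_templates,
)
from sparsenets.simulate import subject_seeds, subject_signal_matrix


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale study: 16³ grid, 4 planted networks, 60 time points."""
    return SyntheticSpec(
        grid_shape=(16, 16, 16),
        n_networks=4,
        n_timepoints=60,
        blob_size=60,
        snr=5.0,
        n_subjects=2,
        jitter=1,
        seed=202,
    )


@pytest.fixture(scope="session")
def small_templates(small_spec):
    return generate_templates(small_spec)


@pytest.fixture(scope="session")
def small_mask(small_spec):
    return generate_mask(small_spec)


@pytest.fixture(scope="session")
def small_subject(small_spec, small_templates):
    return generate_subject(small_spec, small_templates, subject_seeds(small_spec)[0])


@pytest.fixture(scope="session")
def small_signals(small_subject, small_mask):
    return subject_signal_matrix(small_subject, small_mask)


@pytest.fixture()
def cube_mask():
    """Fully-true 4×4×4 mask for shape-level tests."""
    return BrainMask(grid=np.ones((4, 4, 4), dtype=bool))
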