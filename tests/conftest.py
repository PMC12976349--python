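import numpy as np
import pytest

from synthecv import (CohortConfig, build_geometry, render_t1_pair,
                      sample_subject, segment_oracle)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, partial-volume-free cohort: exact tissue values."""
    return CohortConfig(n_subjects=50, seed=101, noise_sd_fraction=0.0,
                        partial_volume=False)


@pytest.fixture(scope="session")
def noisy_config():
    """Default realism: 2% voxel noise plus one-voxel partial-volume band."""
    return CohortConfig(n_subjects=50, seed=101, noise_sd_fraction=0.02,
                        partial_volume=True)


def make_scene(config, index):
    """(subject, labels, native map, post map) for one phantom subject."""
    subject = sample_subject(config, index)
    labels = build_geometry(subject)
    native, post = render_t1_pair(labels, subject, config)
    return subject, labels, native, post


@pytest.fixture(scope="session")
def clean_scene(clean_config):
    return make_scene(clean_config, 0)


@pytest.fixture(scope="session")
def noisy_scene(noisy_config):
    return make_scene(noisy_config, 0)


@pytest.fixture(scope="session")
def oracle_masks(clean_scene):
    return segment_oracle(clean_scene[1])


def random_mask(rng, shape=(16, 16), p=0.5):
    return rng.random(shape) < p
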