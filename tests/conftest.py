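"""Shared fixtures: packaged condition profiles and pre-generated images.

Image generation plus segmentation is the slow part of the suite, so the
noise-free and noisy wild-type fields are generated once per session.
"""

import dataclasses

import pytest
from hypothesis import settings

from hipposcaffold import synthetic
from hipposcaffold.fixture_data import load_profile

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def wt_profile():
    return load_profile("wt")


@pytest.fixture(scope="session")
def ksr1_null_profile():
    return load_profile("ksr1_null")


@pytest.fixture(scope="session")
def clean_wt_profile(wt_profile):
    return dataclasses.replace(wt_profile, noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_field(clean_wt_profile):
    """One noise-free wild-type field with ground truth."""
    return synthetic.generate_cell_image(clean_wt_profile, seed=3)


@pytest.fixture(scope="session")
def noisy_field(wt_profile):
    """One wild-type field at the default noise level."""
    return synthetic.generate_cell_image(wt_profile, seed=3)
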