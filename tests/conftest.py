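"""Shared fixtures: small synthetic datasets regenerated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import ulbpez as u


@pytest.fixture(scope="session")
def binary_feature_set():
    """100 grade-0 + 100 grade-4 images, preprocessed and ULBPEZ-extracted
    at (P, R) = (8, 3) with package defaults.

    Session-scoped: the end-to-end screening checks (SVM on padded token
    vectors, CNN on feature images) share this one extraction pass.
    Returns (padded vectors, feature images, grades).
    """
    images = u.generate_dataset(100, seed=42, grades=(0, 4))
    X, F, y = u.extract_dataset(images)
    return X, F, y


@pytest.fixture(scope="session")
def small_synth_image():
    """One deterministic grade-2 synthetic fundus image."""
    return u.generate(2, seed=7)


@pytest.fixture(scope="session")
def enhanced_and_mask(small_synth_image):
    """Preprocessed (enhanced green, FOV mask) pair for the shared image."""
    return u.preprocess(small_synth_image.image)
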