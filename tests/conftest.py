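"""Shared fixtures: one small synthetic scene reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from sectionfuse.synthetic import make_tissue_image


@pytest.fixture(scope="session")
def scene():
    """Small histology-like scene with ground truth, shared by read-only tests."""
    return make_tissue_image(7, size_px=512, n_glands=10, n_landmarks=40)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
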