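"""Shared fixtures: synthetic crops, a subject-structured cohort with its
feature matrix, and small geometry fixtures reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from histospec.config import GridConfig, RunConfig
from histospec.pipeline import extract_feature_matrix
from histospec.synthetic import (
    TissueSpec,
    generate_he_image,
    generate_paired_dataset,
    tissue_spec_for_class,
)


@pytest.fixture(scope="session")
def normal_crop():
    """One normal-grade crop with ground truth (fixed seed)."""
    return generate_he_image(tissue_spec_for_class("normal", seed=5))


@pytest.fixture(scope="session")
def dysplasia_crop():
    return generate_he_image(tissue_spec_for_class("dysplasia", seed=5))


@pytest.fixture(scope="session")
def sparse_spec():
    """Non-overlapping nuclei: wide spacing, nearly elliptical outlines."""
    return TissueSpec(
        pathology_class="normal",
        n_nuclei=30,
        nucleus_axes_mean=13.0,
        nucleus_axes_sd=1.2,
        boundary_irregularity=0.04,
        crowding=0.65,
        seed=9,
    )


@pytest.fixture(scope="session")
def small_grid():
    """Reduced hyperparameter grid keeping nested CV fast in tests."""
    return GridConfig(
        m_grid=(1, 5, 10, 30, 50),
        c_exponents=(-3, -1, 1, 3),
        gamma_exponents=(-3, -1, 1, 3),
    )


@pytest.fixture(scope="session")
def cohort_bundle():
    """Default 10-subject cohort (two images per class per subject)."""
    return generate_paired_dataset(n_subjects=10, images_per_class=2, seed=11)


@pytest.fixture(scope="session")
def cohort_features(cohort_bundle):
    """Feature matrix of the cohort: the expensive shared computation."""
    return extract_feature_matrix(cohort_bundle, RunConfig())


def sierpinski_carpet(depth: int) -> np.ndarray:
    """Triadic Sierpinski carpet, closed-form dimension log 8 / log 3."""
    img = np.ones((3**depth, 3**depth), dtype=bool)

    def carve(x0: int, y0: int, s: int) -> None:
        if s < 3:
            return
        t = s // 3
        img[x0 + t : x0 + 2 * t, y0 + t : y0 + 2 * t] = False
        for i in range(3):
            for j in range(3):
                if not (i == 1 and j == 1):
                    carve(x0 + i * t, y0 + j * t, t)

    carve(0, 0, 3**depth)
    return img
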