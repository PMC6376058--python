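import numpy as np
import pandas as pd
import pytest

from radiomics_repro.cohort import CohortSpec, generate_cohort
from radiomics_repro.pipeline import extract_cohort_features


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort at the default study conditions (8 patients)."""
    spec = CohortSpec(n_patients=8, rng_seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    return extract_cohort_features(small_cohort)


@pytest.fixture(scope="session")
def zero_perturb_table():
    """Identity-readings cohort: all three delineations coincide."""
    spec = CohortSpec(
        n_patients=5,
        inter_reader_perturb=0.0,
        intra_reader_perturb=0.0,
        rng_seed=7,
    )
    return extract_cohort_features(generate_cohort(spec))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_small_roi(rng, max_side=6, n_levels=4):
    """A random discretizable ROI on a grid of side <= max_side.

    Returns (values, mask) where values are level * 20 - 10 so that
    discretization with bin width 20 recovers the intended levels, and the
    mask is a random connected region.
    """
    from scipy import ndimage

    h = rng.integers(2, max_side + 1)
    w = rng.integers(2, max_side + 1)
    while True:
        mask = rng.random((h, w)) < 0.75
        if mask.sum() < 2:
            continue
        lab, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (np.argmax(sizes) + 1)
        if mask.sum() >= 2:
            break
    levels = rng.integers(1, n_levels + 1, size=(h, w))
    values = levels * 20.0 - 10.0
    return values, mask
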