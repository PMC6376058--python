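"""Texture matrices against exhaustive enumeration oracles, and feature checks."""

import numpy as np
import pytest

from radiomics_repro.features import (
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from radiomics_repro.features.matrices import ANGLES_2D
from radiomics_repro.preprocess import discretize

from .conftest import random_small_roi
from .oracles import (
    glcm_enumeration,
    glrlm_enumeration,
    glszm_enumeration,
    ngtdm_enumeration,
)


def _disc(levels, mask=None):
    levels = np.asarray(levels)
    values = levels * 20.0 - 10.0
    if mask is None:
        mask = np.ones(levels.shape, dtype=bool)
    return discretize(values, 20.0, mask=mask)


CHECKER = np.array([[1, 2], [2, 1]])


class TestMatricesAgainstOracles:
    def test_checkerboard_glcm_pairs(self):
        tm = build_glcm(_disc(CHECKER))
        # 0deg and 90deg give only (1,2)/(2,1); diagonals give (1,1), (2,2)
        m = tm.matrix
        # one horizontal + one vertical (1,2) pair per row/column, symmetrized
        assert m[0, 1] == m[1, 0] == 4
        assert m[0, 0] == 2 and m[1, 1] == 2  # one diagonal pair each
        np.testing.assert_array_equal(
            m, glcm_enumeration(_disc(CHECKER).levels, np.ones((2, 2), bool))
        )

    def test_single_horizontal_run(self):
        d = _disc(np.array([[1, 1, 1, 1]]))
        tm = build_glrlm(d, angles=((0, 1),))
        assert tm.matrix.shape == (1, 4)
        assert tm.matrix[0, 3] == 1 and tm.matrix.sum() == 1
        feats_dir = glrlm_features(tm)
        assert feats_dir["LRE"] == pytest.approx(16.0)
        assert feats_dir["SRE"] == pytest.approx(1.0 / 16.0)

    def test_two_blob_zone_sizes(self):
        levels = np.array(
            [
                [1, 1, 2, 2, 2],
                [1, 2, 2, 1, 2],
            ]
        )
        d = _disc(levels)
        tm = build_glszm(d)
        oracle = glszm_enumeration(d.levels, d.mask)
        np.testing.assert_array_equal(tm.matrix, oracle)

    @pytest.mark.parametrize("seed", range(30))
    def test_exhaustive_small_roi_equivalence(self, seed):
        """All four matrices equal brute-force enumeration on ROIs <= 6x6."""
        rng = np.random.default_rng(seed)
        values, mask = random_small_roi(rng)
        d = discretize(values, 20.0, mask=mask)
        np.testing.assert_array_equal(
            build_glcm(d).matrix, glcm_enumeration(d.levels, mask)
        )
        np.testing.assert_array_equal(
            build_glrlm(d).matrix, glrlm_enumeration(d.levels, mask)
        )
        np.testing.assert_array_equal(
            build_glszm(d).matrix, glszm_enumeration(d.levels, mask)
        )
        n_i, s_i = ngtdm_enumeration(d.levels, mask)
        tm = build_ngtdm(d)
        np.testing.assert_array_equal(tm.matrix[:, 0], n_i)
        np.testing.assert_allclose(tm.matrix[:, 1], s_i, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_normalisation_and_symmetry(self, seed):
        rng = np.random.default_rng(100 + seed)
        values, mask = random_small_roi(rng)
        d = discretize(values, 20.0, mask=mask)
        for build in (build_glcm, build_glrlm, build_glszm):
            tm = build(d)
            assert np.all(tm.matrix >= 0)
            assert tm.normalized.sum() == pytest.approx(1.0)
        glcm = build_glcm(d)
        np.testing.assert_array_equal(glcm.matrix, glcm.matrix.T)


class TestGLCMFeatures:
    def test_constant_roi(self):
        tm = build_glcm(_disc(np.ones((3, 3), dtype=int)))
        f = glcm_features(tm)
        assert f["JointEnergy"] == pytest.approx(1.0)
        assert f["MaximumProbability"] == pytest.approx(1.0)
        assert f["JointEntropy"] == pytest.approx(0.0)
        assert f["Contrast"] == pytest.approx(0.0)

    def test_checkerboard_contrast_dissimilarity_by_direct_sum(self):
        tm = build_glcm(_disc(CHECKER))
        p = tm.normalized
        i, j = np.meshgrid([1, 2], [1, 2], indexing="ij")
        f = glcm_features(tm)
        assert f["Contrast"] == pytest.approx(float((p * (i - j) ** 2).sum()))
        assert f["Dissimilarity"] == pytest.approx(
            float((p * np.abs(i - j)).sum())
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_homogeneity_family_bounded(self, seed):
        rng = np.random.default_rng(200 + seed)
        values, mask = random_small_roi(rng)
        f = glcm_features(build_glcm(discretize(values, 20.0, mask=mask)))
        for name in ("Homogeneity1", "Homogeneity2", "IDM", "IDMN"):
            assert 0.0 < f[name] <= 1.0

    def test_correlation_parameterizations_coincide_on_symmetric_matrix(self, rng):
        values, mask = random_small_roi(rng, max_side=6, n_levels=5)
        f = glcm_features(build_glcm(discretize(values, 20.0, mask=mask)))
        if np.isfinite(f["Correlation1"]):
            assert f["Correlation1"] == pytest.approx(f["Correlation2"], abs=1e-10)


class TestRunZoneFeatures:
    def test_constant_roi_single_zone(self):
        n = 4
        tm = build_glszm(_disc(np.ones((n, n), dtype=int)))
        f = glszm_features(tm)
        assert f["ZP"] == pytest.approx(1.0 / n**2)
        assert f["LAE"] == pytest.approx(float(n**4))

    def test_checkerboard_zones_all_singletons_under_4_connectivity(self):
        # under 8-connectivity a checkerboard's like pixels touch diagonally,
        # so the fully fragmented case needs 4-connectivity
        levels = np.indices((4, 4)).sum(axis=0) % 2 + 1
        f = glszm_features(build_glszm(_disc(levels), connectivity=4))
        assert f["SAE"] == pytest.approx(1.0)
        assert f["ZP"] == pytest.approx(1.0)

    def test_distinct_levels_zones_all_singletons(self):
        levels = np.arange(1, 10).reshape(3, 3)
        f = glszm_features(build_glszm(_disc(levels)))
        assert f["SAE"] == pytest.approx(1.0)
        assert f["ZP"] == pytest.approx(1.0)

    def test_constant_roi_run_percentage_below_one(self):
        f = glrlm_features(build_glrlm(_disc(np.ones((4, 4), dtype=int))))
        assert f["RP"] < 1.0

    def test_all_distinct_levels_degenerate_runs(self):
        levels = np.arange(1, 10).reshape(3, 3)
        f = glrlm_features(build_glrlm(_disc(levels)))
        assert f["SRE"] == pytest.approx(1.0)
        assert f["LRE"] == pytest.approx(1.0)
        assert f["RP"] == pytest.approx(1.0)


class TestNGTDM:
    def test_flat_image_contrast_zero_coarseness_capped(self):
        f = ngtdm_features(build_ngtdm(_disc(np.ones((4, 4), dtype=int) * 2)))
        assert f["Contrast"] == pytest.approx(0.0)
        assert f["Coarseness"] == pytest.approx(1e6)

    def test_bright_center_hand_enumeration(self):
        levels = np.ones((3, 3), dtype=int)
        levels[1, 1] = 3
        d = _disc(levels)
        tm = build_ngtdm(d)
        n_i, s_i = ngtdm_enumeration(d.levels, d.mask)
        np.testing.assert_array_equal(tm.matrix[:, 0], n_i)
        np.testing.assert_allclose(tm.matrix[:, 1], s_i, rtol=1e-12)
        # center: |3 - mean(eight 1s)| = 2; corners: |1 - (2+3/...)|
        assert s_i[2] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_busyness_complexity_nonnegative_on_fuzzed_rois(self, seed):
        rng = np.random.default_rng(300 + seed)
        values, mask = random_small_roi(rng, n_levels=6)
        f = ngtdm_features(build_ngtdm(discretize(values, 20.0, mask=mask)))
        assert f["Busyness"] >= 0.0
        assert f["Complexity"] >= 0.0
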