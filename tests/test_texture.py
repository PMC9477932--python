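"""Texture matrices and features against exhaustive-enumeration oracles."""

import numpy as np
import pytest

from fetrad.features import (compute_glcm, compute_glrlm, compute_glszm,
                             discretize, glcm_features, glrlm_features,
                             glszm_features, IN_PLANE_DIRECTIONS)
from fetrad.features.texture import TextureMatrix

from oracles import (DIRECTIONS, glcm_counts_oracle, glrlm_counts_oracle,
                     glszm_counts_oracle, imc2_oracle, inn_oracle)


def matrix_to_dict(m: TextureMatrix) -> dict:
    out = {}
    for i, g in enumerate(m.gray_levels):
        for j, c in enumerate(m.col_values):
            if m.counts[i, j]:
                out[(int(g), int(c))] = int(m.counts[i, j])
    return out


class TestDiscretize:
    def test_same_bin(self, droi_factory):
        values = np.array([[1.61, 1.69]])
        mask = np.ones((1, 2), dtype=bool)
        droi = discretize(values, mask, bin_width=0.1)
        assert set(droi.levels[mask]) == {17}  # interval [1.6, 1.7)

    def test_consecutive_levels(self):
        values = np.array([[1.65, 1.75, 1.85]])
        droi = discretize(values, np.ones((1, 3), dtype=bool))
        assert droi.levels[0].tolist() == [17, 18, 19]

    def test_constant_roi_single_level(self):
        droi = discretize(np.full((3, 3), 2.0), np.ones((3, 3), dtype=bool))
        assert droi.occupied_levels.size == 1

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            discretize(np.ones((2, 2)), np.ones((2, 2), dtype=bool), bin_width=0)

    def test_scale_consistency(self):
        # scaling SUV and background jointly leaves TBR levels unchanged
        rng = np.random.default_rng(0)
        suv = 1.0 + rng.random((4, 4)) * 2
        mask = np.ones((4, 4), dtype=bool)
        bg = 1.1
        for c in (1.0, 3.7):
            droi = discretize(c * suv / (c * bg), mask)
            base = discretize(suv / bg, mask)
            assert np.array_equal(droi.levels, base.levels)


class TestGLCM:
    def test_strip_pairs(self, droi_factory):
        droi = droi_factory([[1, 1, 2, 2]])
        m = compute_glcm(droi, directions=((0, 1),))[0]
        # unordered pair totals: (1,1): 2, (1,2): 2, (2,2): 2 -> 1/3 each
        assert matrix_to_dict(m) == {(1, 1): 2, (1, 2): 1, (2, 1): 1, (2, 2): 2}
        p = m.probabilities
        assert p.sum() == pytest.approx(1.0)
        assert p[0, 0] == pytest.approx(1 / 3)
        assert p[0, 1] + p[1, 0] == pytest.approx(1 / 3)

    def test_constant_roi(self, droi_factory):
        droi = droi_factory(np.ones((3, 3)))
        for m in compute_glcm(droi):
            p = m.probabilities
            assert p.shape == (1, 1) and p[0, 0] == 1.0

    def test_checkerboard_horizontal(self, droi_factory):
        board = np.indices((4, 4)).sum(axis=0) % 2 + 1
        droi = droi_factory(board)
        m = compute_glcm(droi, directions=((0, 1),))[0]
        p = m.probabilities
        assert p[0, 1] + p[1, 0] == pytest.approx(1.0)
        assert p[0, 0] == 0 and p[1, 1] == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_random_roi_matches_oracle(self, droi_factory, seed):
        rng = np.random.default_rng(seed)
        pattern = rng.integers(1, 4, size=(4, 4))
        mask = rng.random((4, 4)) > 0.3
        if mask.sum() < 2:
            mask[:2, 0] = True
        droi = droi_factory(pattern, mask)
        levels = np.where(mask, pattern, 0).tolist()
        for m, d in zip(compute_glcm(droi), IN_PLANE_DIRECTIONS):
            oracle = glcm_counts_oracle(levels, mask.tolist(), d)
            assert matrix_to_dict(m) == {k: v for k, v in oracle.items()}

    def test_symmetry(self, droi_factory):
        rng = np.random.default_rng(1)
        droi = droi_factory(rng.integers(1, 4, (5, 5)))
        for m in compute_glcm(droi):
            assert np.array_equal(m.counts, m.counts.T)


class TestGLCMFeatures:
    def test_constant_roi_imc2_zero(self, droi_factory):
        droi = droi_factory(np.ones((3, 3)))
        feats = glcm_features(compute_glcm(droi))
        assert feats["glcm_imc2"] == 0.0
        assert feats["glcm_energy"] == 1.0

    def test_independent_marginals_imc2_zero(self):
        # constructed product distribution: HXY2 == HXY -> IMC2 = 0
        px = np.array([0.3, 0.7])
        P = np.outer(px, px)
        m = TextureMatrix(kind="GLCM", counts=P, gray_levels=np.array([1, 2]),
                          col_values=np.array([1, 2]))
        feats = glcm_features([m])
        assert feats["glcm_imc2"] == pytest.approx(0.0, abs=1e-12)

    def test_imc2_against_entropy_oracle(self):
        P = np.array([[0.4, 0.1], [0.1, 0.4]])
        m = TextureMatrix(kind="GLCM", counts=P, gray_levels=np.array([1, 2]),
                          col_values=np.array([1, 2]))
        feats = glcm_features([m])
        assert feats["glcm_imc2"] == pytest.approx(imc2_oracle(P), abs=1e-10)

    def test_imc2_range(self, droi_factory):
        rng = np.random.default_rng(2)
        for _ in range(10):
            droi = droi_factory(rng.integers(1, 5, (5, 5)))
            v = glcm_features(compute_glcm(droi))["glcm_imc2"]
            assert 0.0 <= v < 1.0


class TestGLRLM:
    def test_single_run(self, droi_factory):
        droi = droi_factory([[1, 1, 1, 1]])
        m = compute_glrlm(droi, directions=((0, 1),))[0]
        assert matrix_to_dict(m) == {(1, 4): 1}
        feats = glrlm_features([m], droi.n_voxels)
        assert feats["glrlm_run_percentage"] == pytest.approx(0.25)

    def test_alternating_strip(self, droi_factory):
        droi = droi_factory([[1, 2, 1, 2]])
        m = compute_glrlm(droi, directions=((0, 1),))[0]
        feats = glrlm_features([m], droi.n_voxels)
        assert feats["glrlm_short_run_emphasis"] == pytest.approx(1.0)

    def test_printed_example_rln(self, droi_factory):
        droi = droi_factory([[1, 1, 2], [1, 1, 2], [3, 3, 3]])
        m = compute_glrlm(droi, directions=((0, 1),))[0]
        assert matrix_to_dict(m) == {(1, 2): 2, (2, 1): 2, (3, 3): 1}
        feats = glrlm_features([m], droi.n_voxels)
        assert feats["glrlm_run_length_nonuniformity"] == pytest.approx(9 / 25)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_roi_matches_oracle(self, droi_factory, seed):
        rng = np.random.default_rng(100 + seed)
        pattern = rng.integers(1, 4, size=(4, 4))
        mask = rng.random((4, 4)) > 0.3
        if not mask.any():
            mask[0, 0] = True
        droi = droi_factory(pattern, mask)
        levels = np.where(mask, pattern, 0).tolist()
        for m, d in zip(compute_glrlm(droi), IN_PLANE_DIRECTIONS):
            oracle = glrlm_counts_oracle(levels, mask.tolist(), d)
            assert matrix_to_dict(m) == {k: v for k, v in oracle.items()}


class TestGLSZM:
    def test_constant_roi_single_zone(self, droi_factory):
        droi = droi_factory(np.ones((3, 3)))
        m = compute_glszm(droi)
        assert matrix_to_dict(m) == {(1, 9): 1}

    def test_strip_zones(self, droi_factory):
        droi = droi_factory([[1, 1, 2, 2, 1]])
        m = compute_glszm(droi)
        assert matrix_to_dict(m) == {(1, 2): 1, (2, 2): 1, (1, 1): 1}
        feats = glszm_features(m, droi.n_voxels)
        assert feats["glszm_intensity_nonuniformity_normalized"] == \
            pytest.approx(5 / 9)

    def test_checkerboard_eight_connectivity(self, droi_factory):
        board = np.indices((4, 4)).sum(axis=0) % 2 + 1
        m = compute_glszm(droi_factory(board))
        # diagonal touching merges same-level cells: two zones of size 8
        assert matrix_to_dict(m) == {(1, 8): 1, (2, 8): 1}

    @pytest.mark.parametrize("seed", range(8))
    def test_random_roi_matches_oracle(self, droi_factory, seed):
        rng = np.random.default_rng(200 + seed)
        pattern = rng.integers(1, 4, size=(4, 4))
        mask = rng.random((4, 4)) > 0.3
        if not mask.any():
            mask[0, 0] = True
        droi = droi_factory(pattern, mask)
        levels = np.where(mask, pattern, 0).tolist()
        oracle = glszm_counts_oracle(levels, mask.tolist())
        assert matrix_to_dict(compute_glszm(droi)) == dict(oracle)
        feats = glszm_features(compute_glszm(droi), droi.n_voxels)
        assert feats["glszm_intensity_nonuniformity_normalized"] == \
            pytest.approx(inn_oracle(oracle))


class TestGLSZMFeatures:
    def test_single_gray_level_inn_is_one(self, droi_factory):
        droi = droi_factory([[1, 0, 1], [0, 1, 0], [1, 0, 1]],
                            mask=[[1, 0, 1], [0, 1, 0], [1, 0, 1]])
        feats = glszm_features(compute_glszm(droi), droi.n_voxels)
        assert feats["glszm_intensity_nonuniformity_normalized"] == 1.0

    def test_two_balanced_levels(self, droi_factory):
        droi = droi_factory([[1, 1, 2, 2]])
        feats = glszm_features(compute_glszm(droi), 4)
        assert feats["glszm_intensity_nonuniformity_normalized"] == \
            pytest.approx(0.5)

    def test_inn_range(self, droi_factory):
        rng = np.random.default_rng(4)
        for _ in range(10):
            droi = droi_factory(rng.integers(1, 5, (5, 5)))
            v = glszm_features(compute_glszm(droi), droi.n_voxels)
            assert 0.0 < v["glszm_intensity_nonuniformity_normalized"] <= 1.0
            assert 0.0 < v["glszm_zone_percentage"] <= 1.0


class TestRotationInvariance:
    @pytest.mark.parametrize("seed", range(4))
    def test_direction_averaged_features_invariant_under_rot90(
            self, droi_factory, seed):
        rng = np.random.default_rng(300 + seed)
        pattern = rng.integers(1, 4, size=(5, 5))
        a = droi_factory(pattern)
        b = droi_factory(np.rot90(pattern))
        fa = glcm_features(compute_glcm(a))
        fb = glcm_features(compute_glcm(b))
        for k in fa:
            assert fa[k] == pytest.approx(fb[k], abs=1e-12)
        ra = glrlm_features(compute_glrlm(a), a.n_voxels)
        rb = glrlm_features(compute_glrlm(b), b.n_voxels)
        for k in ra:
            assert ra[k] == pytest.approx(rb[k], abs=1e-12)
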