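import numpy as np
import pytest

from oracles import glcm_bruteforce, glrlm_bruteforce, glszm_bruteforce, ngtdm_bruteforce
from petrad.texture_features import (
    DIRECTIONS_3D,
    EPS,
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    NGTDM_FEATURE_NAMES,
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    texture_features,
)

from conftest import make_discretized, random_roi


class TestDirectionSet:
    def test_thirteen_directions(self):
        assert len(DIRECTIONS_3D) == 13

    def test_no_negated_duplicates(self):
        negs = {tuple(-c for c in d) for d in DIRECTIONS_3D}
        assert negs.isdisjoint(set(DIRECTIONS_3D))

    def test_unit_voxel_displacement(self):
        for d in DIRECTIONS_3D:
            assert d != (0, 0, 0)
            assert all(c in (-1, 0, 1) for c in d)


def _constant_roi(l=12, ng=4):
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask.ravel()[:l] = True
    mask = mask.reshape(4, 4, 4)
    return make_discretized(np.ones((4, 4, 4)), mask, ng)


class TestGLCM:
    def test_constant_roi_single_entry(self):
        d = make_discretized(np.ones((3, 3, 3)), np.ones((3, 3, 3), bool), 4)
        p = build_glcm(d)
        assert p[0, 0] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)
        assert np.count_nonzero(p) == 1

    def test_two_voxel_pair_symmetry(self):
        levels = np.array([1, 2]).reshape(2, 1, 1)
        d = make_discretized(levels, np.ones((2, 1, 1), bool), 2)
        p = build_glcm(d)
        assert p[0, 1] == pytest.approx(0.5)
        assert p[1, 0] == pytest.approx(0.5)

    def test_single_voxel_roi_errors(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        d = make_discretized(np.ones((3, 3, 3)), mask, 2)
        with pytest.raises(ValueError, match="GLCM undefined"):
            build_glcm(d)

    def test_symmetry_and_normalization_random(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            d = random_roi(rng)
            p = build_glcm(d)
            np.testing.assert_allclose(p, p.T)
            assert p.sum() == pytest.approx(1.0)
            assert (p >= 0).all()

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            d = random_roi(rng)
            expected = glcm_bruteforce(d.levels, d.mask, d.ng, DIRECTIONS_3D)
            np.testing.assert_allclose(build_glcm(d), expected, atol=1e-12)


class TestGLCMFeatures:
    def test_constant_roi_identities(self):
        # homogeneity features peak and entropy vanishes for a uniform ROI
        f = glcm_features(build_glcm(_constant_roi()))
        assert f["glcm_inverse_difference_moment"] == pytest.approx(1.0)
        assert f["glcm_inverse_difference"] == pytest.approx(1.0)
        assert f["glcm_entropy"] == pytest.approx(0.0)

    def test_checkerboard_hand_computed(self):
        # 4x4x1 checkerboard with the single in-plane offset (1,0,0):
        # every horizontal neighbor pair alternates levels, so the hand-built
        # GLCM is [[0, .5], [.5, 0]]
        levels = np.indices((4, 4, 1)).sum(axis=0) % 2 + 1
        d = make_discretized(levels, np.ones((4, 4, 1), bool), 2)
        p = build_glcm(d, directions=((1, 0, 0),))
        np.testing.assert_allclose(p, [[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(p)
        assert f["glcm_contrast"] == pytest.approx(1.0)
        assert f["glcm_dissimilarity"] == pytest.approx(1.0)
        assert f["glcm_entropy"] == pytest.approx(1.0)  # two equal outcomes
        assert f["glcm_inverse_difference"] == pytest.approx(0.5)
        assert f["glcm_inverse_difference_moment"] == pytest.approx(0.5)
        assert f["glcm_joint_average"] == pytest.approx(1.5)
        assert f["glcm_sum_entropy"] == pytest.approx(0.0)  # all sums equal 3
        assert f["glcm_difference_entropy"] == pytest.approx(0.0)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            glcm_features(np.ones((3, 3)))

    def test_feature_count_and_names(self):
        f = glcm_features(build_glcm(_constant_roi()))
        assert set(f) == set(GLCM_FEATURE_NAMES)
        assert len(f) == 26


class TestGLRLM:
    def test_single_line_run(self):
        l = 5
        d = make_discretized(np.ones((1, 1, l)), np.ones((1, 1, l), bool), 2)
        mat = build_glrlm(d, directions=((0, 0, 1),))
        assert mat[0, l - 1] == 1
        assert mat.sum() == 1
        f = glrlm_features(mat)
        assert f["glrlm_sre"] == pytest.approx(1.0 / l**2)
        assert f["glrlm_rpc"] == pytest.approx(1.0 / l)

    def test_all_runs_length_one(self):
        # 2x2x1 block of four distinct levels: no neighbors share a level
        levels = np.array([[1, 2], [3, 4]]).reshape(2, 2, 1)
        d = make_discretized(levels, np.ones((2, 2, 1), bool), 4)
        f = glrlm_features(build_glrlm(d))
        assert f["glrlm_sre"] == pytest.approx(1.0)
        assert f["glrlm_rpc"] == pytest.approx(1.0)

    def test_runs_break_at_mask_boundaries(self):
        levels = np.ones((1, 1, 5))
        mask = np.array([1, 1, 0, 1, 1], bool).reshape(1, 1, 5)
        d = make_discretized(levels, mask, 2)
        mat = build_glrlm(d, directions=((0, 0, 1),))
        assert mat[0, 1] == 2  # two runs of length 2

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            d = random_roi(rng)
            expected = glrlm_bruteforce(d.levels, d.mask, d.ng, DIRECTIONS_3D)
            np.testing.assert_array_equal(build_glrlm(d), expected)

    def test_conservation(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            d = random_roi(rng)
            mat = build_glrlm(d)
            lengths = np.arange(1, mat.shape[1] + 1)
            assert np.sum(mat * lengths) == 13 * d.voxel_count

    def test_feature_names(self):
        d = _constant_roi()
        f = glrlm_features(build_glrlm(d))
        assert set(f) == set(GLRLM_FEATURE_NAMES)
        assert len(f) == 11


class TestGLSZM:
    def test_constant_roi_single_zone(self):
        l = 12
        d = _constant_roi(l=l)
        mat = build_glszm(d)
        assert mat.sum() == 1
        f = glszm_features(mat)
        assert f["glszm_zp"] == pytest.approx(1.0 / l)

    def test_two_disjoint_islands(self):
        levels = np.zeros((5, 1, 1), dtype=int)
        mask = np.zeros((5, 1, 1), bool)
        levels[0], levels[4] = 1, 2
        mask[0], mask[4] = True, True
        d = make_discretized(levels, mask, 2)
        mat = build_glszm(d)
        assert mat[0, 0] == 1 and mat[1, 0] == 1
        assert mat.sum() == 2

    def test_diagonal_voxels_form_one_zone(self):
        # 26-connectivity joins the two diagonal voxels
        levels = np.ones((2, 2, 2), dtype=int)
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        d = make_discretized(levels, mask, 2)
        assert build_glszm(d)[0, 1] == 1

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            d = random_roi(rng)
            expected = glszm_bruteforce(d.levels, d.mask, d.ng)
            np.testing.assert_array_equal(build_glszm(d), expected)

    def test_conservation(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            d = random_roi(rng)
            mat = build_glszm(d)
            sizes = np.arange(1, mat.shape[1] + 1)
            assert np.sum(mat * sizes) == d.voxel_count

    def test_feature_names(self):
        f = glszm_features(build_glszm(_constant_roi()))
        assert set(f) == set(GLSZM_FEATURE_NAMES)
        assert len(f) == 11


class TestNGTDM:
    def test_constant_roi_coarseness_sentinel(self):
        m = build_ngtdm(_constant_roi())
        assert np.all(m.s == 0)
        f = ngtdm_features(m)
        assert f["ngtdm_coarseness"] == pytest.approx(1.0 / EPS)

    def test_bright_center_hand_window(self):
        # single slice, uniform level 1 except a bright center voxel (level 5)
        levels = np.ones((7, 7, 1), dtype=int)
        levels[3, 3, 0] = 5
        d = make_discretized(levels, np.ones((7, 7, 1), bool), 5)
        m = build_ngtdm(d)
        # center voxel: its 48 neighbors all have level 1 -> s_5 = |5 - 1| = 4
        assert m.s[4] == pytest.approx(4.0)
        # each of the 48 others sees the bright voxel once among its in-mask
        # neighbors; their deviation sums match the brute-force reference
        n, s, scored = ngtdm_bruteforce(d.levels, d.mask, d.ng)
        np.testing.assert_allclose(m.s, s)
        np.testing.assert_array_equal(m.n, n)
        assert m.n_scored == scored

    def test_in_mask_neighbors_only(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            d = random_roi(rng)
            m = build_ngtdm(d)
            n, s, scored = ngtdm_bruteforce(d.levels, d.mask, d.ng)
            np.testing.assert_array_equal(m.n, n)
            np.testing.assert_allclose(m.s, s, atol=1e-9)
            assert m.n_scored == scored

    def test_n_sums_to_scored_voxels(self):
        rng = np.random.default_rng(31)
        d = random_roi(rng)
        m = build_ngtdm(d)
        assert m.n.sum() == m.n_scored

    def test_feature_names(self):
        f = ngtdm_features(build_ngtdm(_constant_roi()))
        assert set(f) == set(NGTDM_FEATURE_NAMES)
        assert len(f) == 5


def test_texture_feature_total():
    rng = np.random.default_rng(37)
    d = random_roi(rng)
    f = texture_features(d)
    assert len(f) == 53
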