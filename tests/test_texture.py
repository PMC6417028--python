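import numpy as np
import pytest

from lesionrad.features.texture import (
    DIRECTIONS_13,
    GLCM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
)

from .conftest import make_discretized, random_discretized
from .oracles import brute_glcm, brute_glrlm, brute_glszm

# classic 4x4 single-slice grid (levels shifted to 1..4); transposed so the
# offset (1, 0, 0) walks along the printed rows
HARALICK_GRID = (np.array([[0, 0, 1, 1],
                           [0, 0, 1, 1],
                           [0, 2, 2, 2],
                           [2, 2, 3, 3]]) + 1).T


class TestGLCMMatrix:
    def test_haralick_hand_counts(self):
        d = make_discretized(HARALICK_GRID, 4)
        mat = glcm_matrix(d, (1, 0, 0)).counts
        expected = np.array([[4, 2, 1, 0],
                             [2, 4, 0, 0],
                             [1, 0, 6, 1],
                             [0, 0, 1, 2]], dtype=float)
        np.testing.assert_array_equal(mat, expected)
        assert mat.sum() == 24

    def test_symmetry_and_normalization(self, rng):
        d = random_discretized(rng)
        for off in DIRECTIONS_13:
            m = glcm_matrix(d, off)
            np.testing.assert_array_equal(m.counts, m.counts.T)
            if not m.degenerate:
                assert m.normalized().sum() == pytest.approx(1.0)

    def test_constant_roi_all_mass_at_origin(self):
        d = make_discretized(np.ones((3, 3), int), 1)
        m = glcm_matrix(d, (1, 0, 0))
        assert m.counts.shape == (1, 1)
        assert m.counts[0, 0] > 0

    def test_single_voxel_degenerate(self):
        levels = np.zeros((3, 3, 3), int)
        levels[1, 1, 1] = 1
        d = make_discretized(levels, 2)
        m = glcm_matrix(d, (1, 0, 0))
        assert m.degenerate
        assert m.counts.sum() == 0

    def test_zero_offset_rejected(self, rng):
        d = random_discretized(rng)
        with pytest.raises(ValueError, match="non-zero"):
            glcm_matrix(d, (0, 0, 0))


class TestGLCMFeatures:
    def test_exactly_27_names(self, rng):
        feats = glcm_features(random_discretized(rng))
        assert set(feats) == set(GLCM_NAMES)
        assert len(feats) == 27

    def test_constant_roi_conventions(self):
        d = make_discretized(np.ones((4, 4), int), 1)
        feats = glcm_features(d)
        assert feats["Contrast"] == 0.0
        assert feats["Correlation"] == 1.0
        assert feats["MaximumProbability"] == 1.0
        assert feats["Entropy"] == 0.0

    def test_haralick_contrast_hand_value(self):
        # from the 24-pair symmetric matrix: 6 pairs at |di|=1 and 2 pairs
        # at |di|=2 give sum p(i,j)(i-j)^2 = (6*1 + 2*4)/24 = 14/24
        d = make_discretized(HARALICK_GRID, 4)
        mat = glcm_matrix(d, (1, 0, 0))
        p = mat.normalized()
        i, j = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
        contrast = float((p * (i - j) ** 2).sum())
        assert contrast == pytest.approx(14.0 / 24.0)

    def test_grey_level_reversal_invariance(self, rng):
        d = random_discretized(rng, n_levels=5)
        rev_levels = np.where(d.mask, d.n_levels + 1 - d.levels, 0)
        d_rev = make_discretized(rev_levels, d.n_levels, mask=d.mask)
        a, b = glcm_features(d), glcm_features(d_rev)
        for name in ("Contrast", "Entropy", "Homogeneity1", "Homogeneity2",
                     "Energy", "Dissimilarity", "DifferenceEntropy"):
            assert b[name] == pytest.approx(a[name], rel=1e-10), name


class TestGLRLM:
    def test_one_dimensional_runs(self):
        row = np.array([[1, 1, 2, 2, 2, 3]])
        d = make_discretized(row, 3)
        mat = glrlm_matrix(d, (0, 1, 0)).counts
        # runs: (1, len 2), (2, len 3), (3, len 1)
        assert mat[0, 1] == 1 and mat[1, 2] == 1 and mat[2, 0] == 1
        assert mat.sum() == 3
        # along the row direction: 3 runs over 6 voxels
        assert mat.sum() / row.size == pytest.approx(0.5)

    def test_constant_row_single_run(self):
        L = 7
        d = make_discretized(np.ones((1, L), int), 1)
        mat = glrlm_matrix(d, (0, 1, 0))
        assert mat.counts.shape == (1, L)
        assert mat.counts[0, L - 1] == 1
        i = np.arange(1, L + 1, dtype=float)
        # single run of length L: LRE = L^2, SRE = 1/L^2
        counts = mat.counts
        assert (counts * i[None, :] ** 2).sum() / counts.sum() == L**2
        assert (counts / i[None, :] ** 2).sum() / counts.sum() == pytest.approx(1 / L**2)

    def test_checkerboard_axis_runs_length_one(self):
        # along the two in-plane axis directions every voxel is its own run
        # (diagonal directions see constant values, so they are excluded)
        x, y = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        board = ((x + y) % 2) + 1
        d = make_discretized(board, 2)
        for off in ((1, 0, 0), (0, 1, 0)):
            mat = glrlm_matrix(d, off).counts
            assert mat.sum() == board.size  # 36 runs of length 1
            assert mat[:, 1:].sum() == 0

    def test_runs_broken_by_mask(self):
        row = np.array([[1, 1, 0, 1, 1]])
        d = make_discretized(row, 1, mask=row > 0)
        mat = glrlm_matrix(d, (0, 1, 0)).counts
        assert mat[0, 1] == 2  # two separate runs of length 2
        assert mat.sum() == 2


class TestGLSZM:
    def test_constant_2x2_roi(self):
        levels = np.zeros((4, 4, 1), int)
        levels[1:3, 1:3, 0] = 1
        d = make_discretized(levels, 1, mask=levels > 0)
        mat = glszm_matrix(d).counts
        assert mat.shape == (1, 4)
        assert mat[0, 3] == 1  # one zone of size 4
        feats = glszm_features(d)
        assert feats["ZonePercentage"] == pytest.approx(1.0 / 4.0)

    def test_diagonal_voxels_single_zone_26conn(self):
        levels = np.zeros((3, 3, 1), int)
        levels[0, 0, 0] = 1
        levels[1, 1, 0] = 1
        d = make_discretized(levels, 1, mask=levels > 0)
        mat = glszm_matrix(d).counts
        assert mat[0, 1] == 1  # one zone of size 2 (diagonal touch)
        assert mat.sum() == 1

    def test_cross_slice_checkerboard_zones(self, rng):
        x, y, z = np.meshgrid(*[np.arange(4)] * 3, indexing="ij")
        board = ((x + y + z) % 2) + 1
        d = make_discretized(board, 2)
        ours = glszm_matrix(d).counts
        oracle = brute_glszm(d.levels, d.mask, 2)
        np.testing.assert_array_equal(ours, oracle)

    def test_exactly_16_names(self, rng):
        feats = glszm_features(random_discretized(rng))
        assert set(feats) == set(GLSZM_NAMES)


class TestBruteForceOracles:
    """Texture matrices must equal naive enumeration on random small ROIs."""

    N_SEEDS = 100

    def test_glcm_matches_pair_enumeration(self):
        for seed in range(self.N_SEEDS):
            rng = np.random.default_rng(seed)
            d = random_discretized(rng)
            off = DIRECTIONS_13[seed % len(DIRECTIONS_13)]
            ours = glcm_matrix(d, off).counts
            oracle = brute_glcm(d.levels, d.mask, off, d.n_levels)
            np.testing.assert_array_equal(ours, oracle, err_msg=f"seed={seed}")

    def test_glrlm_matches_run_enumeration(self):
        for seed in range(self.N_SEEDS):
            rng = np.random.default_rng(seed)
            d = random_discretized(rng)
            off = DIRECTIONS_13[seed % len(DIRECTIONS_13)]
            ours = glrlm_matrix(d, off).counts
            oracle = brute_glrlm(d.levels, d.mask, off, d.n_levels)
            np.testing.assert_array_equal(ours, oracle, err_msg=f"seed={seed}")

    def test_glszm_matches_flood_fill(self):
        for seed in range(self.N_SEEDS):
            rng = np.random.default_rng(seed)
            d = random_discretized(rng)
            ours = glszm_matrix(d).counts
            oracle = brute_glszm(d.levels, d.mask, d.n_levels)
            np.testing.assert_array_equal(ours, oracle, err_msg=f"seed={seed}")


def test_all_features_finite_on_fuzzed_rois():
    for seed in range(200):
        rng = np.random.default_rng(1000 + seed)
        d = random_discretized(rng, n_levels=int(rng.integers(2, 8)))
        for feats in (glcm_features(d), glrlm_features(d), glszm_features(d)):
            assert all(np.isfinite(v) for v in feats.values()), f"seed={seed}"


def test_rotation_invariance_of_direction_averaged_features(rng):
    # 90-degree rotation in the xy-plane (equal spacing axes): the
    # 13-direction set is closed under it
    levels = np.zeros((8, 8, 4), int)
    mask = rng.uniform(size=(8, 8, 4)) < 0.7
    levels[mask] = rng.integers(1, 6, int(mask.sum()))
    d = make_discretized(levels, 5, mask=mask, spacing=(1, 1, 5))
    rot_levels = np.rot90(levels, axes=(0, 1)).copy()
    rot_mask = np.rot90(mask, axes=(0, 1)).copy()
    d_rot = make_discretized(rot_levels, 5, mask=rot_mask, spacing=(1, 1, 5))
    for fn in (glcm_features, glrlm_features, glszm_features):
        a, b = fn(d), fn(d_rot)
        for name in a:
            assert b[name] == pytest.approx(a[name], rel=1e-9), (fn.__name__, name)
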