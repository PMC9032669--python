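"""Rotation-invariant uniform LBP: codes, uniformity, histograms, cell grids."""

import numpy as np
import pytest

from weedvision.lbp import (
    LBPConfig, TABLE_CONFIGS, binary_pattern, cell_grid_features,
    circular_neighbors, feature_length, featurize_patch, lbp_code,
    riu2_code, riu2_histogram, to_grayscale, uniformity,
)

WORKED_PATTERN = np.array([1, 1, 1, 1, 0, 0, 1, 0])  # b_0 first


def bits_of(value: int, width: int = 8) -> np.ndarray:
    return np.array([(value >> p) & 1 for p in range(width)])


def naive_transitions(bits) -> int:
    """Independent circular 0<->1 transition scan."""
    n = len(bits)
    return sum(bits[p] != bits[(p + 1) % n] for p in range(n))


class TestCodes:
    def test_worked_example_code(self):
        """The textbook 3×3 window with centre 77 produces pattern 11110010 -> 79."""
        assert lbp_code(WORKED_PATTERN) == 79

    def test_worked_example_from_window(self):
        neighbors = np.array([80, 90, 100, 77, 60, 50, 95, 40])
        pattern = binary_pattern(77, neighbors)
        np.testing.assert_array_equal(pattern, WORKED_PATTERN)
        assert lbp_code(pattern) == 79

    def test_tie_counts_as_one(self):
        assert binary_pattern(50, np.full(8, 50)).all()

    def test_all_below_centre_zero_pattern(self):
        pattern = binary_pattern(200, np.arange(8))
        assert not pattern.any()
        assert lbp_code(pattern) == 0

    def test_all_ones_is_full_code(self):
        assert lbp_code(np.ones(8, dtype=int)) == 255
        assert lbp_code(np.ones(16, dtype=int)) == 2**16 - 1


class TestUniformity:
    @pytest.mark.parametrize(
        "bits,expected",
        [
            ([0] * 8, 0),
            ([1] * 8, 0),
            ([1, 1, 0, 0, 1, 1, 1, 1], 2),
            ([1, 0, 1, 0, 1, 0, 1, 0], 8),
            (list(WORKED_PATTERN), 4),
        ],
    )
    def test_known_patterns(self, bits, expected):
        assert uniformity(np.array(bits)) == expected

    def test_riu2_known_values(self):
        assert riu2_code(np.zeros(8, dtype=int)) == 0
        assert riu2_code(np.array([1, 1, 0, 0, 1, 1, 1, 1])) == 6
        assert riu2_code(WORKED_PATTERN) == 9  # U=4 -> non-uniform bin P+1

    def test_exhaustive_patterns_p8(self):
        """All 256 patterns: naive transition scan, 58 uniform, shift invariance."""
        uniform_count = 0
        for value in range(256):
            bits = bits_of(value)
            assert uniformity(bits) == naive_transitions(bits)
            if naive_transitions(bits) <= 2:
                uniform_count += 1
            codes = {riu2_code(np.roll(bits, k)) for k in range(8)}
            assert len(codes) == 1  # rotation (circular shift) invariance
        assert uniform_count == 58
        # uniform patterns land in bins 0..8, all others in bin 9
        for value in range(256):
            bits = bits_of(value)
            if naive_transitions(bits) <= 2:
                assert riu2_code(bits) == bits.sum() <= 8
            else:
                assert riu2_code(bits) == 9


class TestSampling:
    def test_p8_r1_is_the_lattice_neighbourhood(self):
        rng = np.random.default_rng(3)
        gray = rng.integers(0, 256, size=(7, 7)).astype(float)
        nb = circular_neighbors(gray, (3, 3), 8, 1)
        # p=0 east, counter-clockwise; diagonals at distance 1 (classic 3×3)
        expected = [gray[3, 4], gray[2, 4], gray[2, 3], gray[2, 2],
                    gray[3, 2], gray[4, 2], gray[4, 3], gray[4, 4]]
        np.testing.assert_allclose(nb, expected)

    def test_constant_image(self):
        nb = circular_neighbors(np.full((9, 9), 41.0), (4, 4), 16, 2)
        np.testing.assert_allclose(nb, 41.0)

    def test_bilinear_on_linear_ramp_is_exact(self):
        """Bilinear interpolation reproduces a plane exactly at any sample point."""
        rr, cc = np.mgrid[0:11, 0:11]
        plane = 3.0 * rr - 2.0 * cc + 7.0
        nb = circular_neighbors(plane, (5, 5), 16, 2)
        theta = 2 * np.pi * np.arange(16) / 16
        expected = 3.0 * (5 - 2 * np.sin(theta)) - 2.0 * (5 + 2 * np.cos(theta)) + 7.0
        np.testing.assert_allclose(nb, expected, atol=1e-9)

    def test_border_centre_rejected(self):
        with pytest.raises(ValueError):
            circular_neighbors(np.zeros((8, 8)), (0, 4), 8, 1)


class TestHistogram:
    @pytest.mark.parametrize("p,r,bins", [(8, 1, 10), (16, 2, 18), (24, 3, 26)])
    def test_bin_counts(self, p, r, bins):
        rng = np.random.default_rng(p)
        gray = rng.integers(0, 256, size=(20, 20))
        hist = riu2_histogram(gray, p, r)
        assert hist.shape == (bins,)
        assert abs(hist.sum() - 1.0) < 1e-9

    def test_constant_image_mass_in_bin_p(self):
        hist = riu2_histogram(np.full((12, 12), 9), 8, 1)
        assert hist[8] == 1.0 and hist.sum() == 1.0

    @pytest.mark.parametrize("p,r", [(8, 1), (16, 2)])
    def test_matches_naive_per_pixel_loop(self, p, r):
        rng = np.random.default_rng(17)
        gray = rng.integers(0, 256, size=(16, 16)).astype(float)
        margin = int(np.ceil(r))
        codes = [
            riu2_code(binary_pattern(gray[i, j],
                                     circular_neighbors(gray, (i, j), p, r)))
            for i in range(margin, 16 - margin)
            for j in range(margin, 16 - margin)
        ]
        expected = np.bincount(codes, minlength=p + 2).astype(float)
        expected /= expected.sum()
        np.testing.assert_allclose(riu2_histogram(gray, p, r), expected, atol=1e-12)

    def test_matches_skimage_reference(self):
        """Independent cross-check against scikit-image's uniform LBP.

        Compared at (P, R) = (16, 2), where both implementations sample the
        same interpolated circle; the (8, 1) case here is the classic 3×3
        lattice neighbourhood, which scikit-image instead interpolates.
        """
        from skimage.feature import local_binary_pattern

        rng = np.random.default_rng(23)
        gray = rng.integers(0, 256, size=(24, 24))
        sk_codes = local_binary_pattern(gray.astype(np.uint8), 16, 2, method="uniform")
        sk_hist = np.bincount(
            sk_codes[2:-2, 2:-2].astype(int).ravel(), minlength=18
        ).astype(float)
        sk_hist /= sk_hist.sum()
        np.testing.assert_allclose(riu2_histogram(gray, 16, 2), sk_hist, atol=1e-12)

    def test_monotone_grayshift_invariance(self):
        rng = np.random.default_rng(29)
        gray = rng.integers(0, 256, size=(18, 18)).astype(np.int64)
        for p, r in [(8, 1), (24, 3)]:
            np.testing.assert_allclose(
                riu2_histogram(gray, p, r), riu2_histogram(gray + 500, p, r)
            )

    def test_180_degree_rotation_invariance(self):
        rng = np.random.default_rng(31)
        gray = rng.integers(0, 256, size=(20, 20))
        for p, r in [(8, 1), (16, 2)]:
            np.testing.assert_allclose(
                riu2_histogram(gray, p, r), riu2_histogram(np.rot90(gray, 2), p, r)
            )

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            riu2_histogram(np.zeros((2, 2)), 8, 1)


class TestCellGrid:
    @pytest.mark.parametrize("p,r", [(8, 1), (16, 2), (24, 3)])
    @pytest.mark.parametrize("image,cell", TABLE_CONFIGS)
    def test_feature_lengths_for_every_grid(self, p, r, image, cell):
        """Concatenated length is n_cells × (P+2) for every study configuration."""
        cfg = LBPConfig(n_points=p, radius=r, image_size=image, cell_size=cell)
        assert cfg.feature_length == (image // cell) ** 2 * (p + 2)
        assert cfg.feature_length == feature_length(p, image, cell)

    def test_concatenation_order_and_values(self):
        rng = np.random.default_rng(37)
        gray = rng.integers(0, 256, size=(64, 64))
        cfg = LBPConfig(n_points=8, radius=1, image_size=64, cell_size=32)
        vec = cell_grid_features(gray, cfg)
        assert vec.shape == (4 * 10,)
        # first block is the top-left cell's histogram
        np.testing.assert_allclose(vec[:10], riu2_histogram(gray[:32, :32], 8, 1))
        # last block is the bottom-right cell's histogram
        np.testing.assert_allclose(vec[30:], riu2_histogram(gray[32:, 32:], 8, 1))

    def test_per_cell_rotation_invariance(self):
        """Rotating every cell by 90° leaves each cell histogram unchanged."""
        rng = np.random.default_rng(41)
        gray = rng.integers(0, 256, size=(64, 64))
        rotated = gray.copy()
        for r in range(0, 64, 32):
            for c in range(0, 64, 32):
                rotated[r : r + 32, c : c + 32] = np.rot90(gray[r : r + 32, c : c + 32])
        cfg = LBPConfig(n_points=8, radius=1, image_size=64, cell_size=32)
        np.testing.assert_allclose(
            cell_grid_features(gray, cfg), cell_grid_features(rotated, cfg)
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LBPConfig(n_points=8, radius=2)  # not a standard pair
        with pytest.raises(ValueError):
            LBPConfig(image_size=100, cell_size=32)  # not divisible
        with pytest.raises(ValueError):
            LBPConfig(image_size=64, cell_size=64)  # equal sizes absent
        with pytest.raises(ValueError):
            LBPConfig(n_points=24, radius=3, image_size=64, cell_size=4)  # no interior


class TestFeaturizePatch:
    def test_grayscale_conversion(self):
        assert to_grayscale(np.full((2, 2, 3), 255, dtype=np.uint8))[0, 0] == 255
        assert to_grayscale(np.zeros((2, 2, 3), dtype=np.uint8))[0, 0] == 0
        gray_in = np.full((3, 3, 3), 77, dtype=np.uint8)
        assert (to_grayscale(gray_in) == 77).all()

    def test_constant_patch_mass_in_bin_p(self):
        patch = np.full((40, 52, 3), 120, dtype=np.uint8)
        cfg = LBPConfig(n_points=8, radius=1, image_size=64, cell_size=32)
        vec = featurize_patch(patch, cfg).reshape(4, 10)
        np.testing.assert_allclose(vec[:, 8], 1.0)

    def test_deterministic(self):
        rng = np.random.default_rng(43)
        patch = rng.integers(0, 256, size=(50, 70, 3), dtype=np.uint8)
        cfg = LBPConfig(n_points=8, radius=1, image_size=64, cell_size=16)
        np.testing.assert_array_equal(
            featurize_patch(patch, cfg), featurize_patch(patch, cfg)
        )

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            featurize_patch(np.empty((0, 0, 3), dtype=np.uint8),
                            LBPConfig(image_size=64, cell_size=32))
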