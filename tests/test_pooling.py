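import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chdnet.cascade import HyperParams
from chdnet.pooling import (
    HashedMap,
    PyramidFeature,
    binarize,
    extract_features,
    feature_length,
    hash_group,
    high_dispersal,
    local_response_normalize,
    pyramid_histogram,
    rescale_hash,
    vectorize,
)
from chdnet.preprocess import Image


class TestBinarize:
    def test_strictly_positive_only(self):
        m = np.array([[-0.5, 0.0], [0.5, 1e-12]])
        np.testing.assert_array_equal(binarize(m), [[0, 0], [1, 1]])

    def test_all_negative_gives_zeros(self):
        np.testing.assert_array_equal(binarize(np.full((3, 3), -0.5)), 0)

    def test_nt_centered_subtracts_map_mean(self):
        m = np.array([[1.0, 3.0]])  # mean 2: below -> 0, above -> 1
        np.testing.assert_array_equal(binarize(m, "nt_centered"), [[0, 1]])

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), "bogus")


class TestHashGroup:
    def test_all_ones_reach_255_with_v1_8(self):
        hm = hash_group(np.ones((8, 4, 4), dtype=int))
        np.testing.assert_array_equal(hm.pixels, 255)

    def test_all_zeros(self):
        hm = hash_group(np.zeros((8, 4, 4), dtype=int))
        np.testing.assert_array_equal(hm.pixels, 0)

    def test_single_branch_k3_gives_4(self):
        maps = np.zeros((8, 2, 2), dtype=int)
        maps[2] = 1  # k = 3 (1-based) -> weight 2^2
        np.testing.assert_array_equal(hash_group(maps).pixels, 4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hash_group([np.zeros((2, 2)), np.zeros((3, 3))])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_hash_inverts_binary_pattern(self, bits):
        pattern = [(bits >> k) & 1 for k in range(8)]
        maps = np.array([np.full((2, 2), b) for b in pattern])
        word = hash_group(maps).pixels[0, 0]
        assert word == sum(b << k for k, b in enumerate(pattern))
        assert 0 <= word <= 255


class TestRescaleHash:
    def test_full_range_map_unchanged(self):
        px = np.arange(256).reshape(16, 16)
        hm = rescale_hash(HashedMap(px, 0))
        np.testing.assert_array_equal(hm.pixels, px)

    def test_constant_map_becomes_zero(self):
        hm = rescale_hash(HashedMap(np.full((4, 4), 9), 0))
        np.testing.assert_array_equal(hm.pixels, 0)

    def test_round_half_away_from_zero(self):
        # 255/510*255 = 127.5 rounds to 128, not banker's 127
        hm = rescale_hash(HashedMap(np.array([[0, 510, 255]]), 0))
        np.testing.assert_array_equal(hm.pixels, [[0, 255, 128]])

    def test_output_bounds(self, rng):
        px = rng.integers(0, 256, (10, 10))
        out = rescale_hash(HashedMap(px, 0)).pixels
        assert out.min() == 0 and out.max() == 255


class TestPyramidHistogram:
    def test_32x32_depth2_gives_21_cells(self):
        hm = HashedMap(np.zeros((32, 32), dtype=int), 0)
        pf = pyramid_histogram(hm, L=2)
        assert pf.values.shape == (21, 256)

    def test_level0_conserves_pixel_count(self, rng):
        hm = HashedMap(rng.integers(0, 256, (12, 15)), 0)
        pf = pyramid_histogram(hm, L=0)
        assert pf.values.sum() == 12 * 15

    def test_every_level_conserves_pixel_count(self, rng):
        hm = HashedMap(rng.integers(0, 256, (16, 16)), 0)
        pf = pyramid_histogram(hm, L=2)
        offsets = [0, 1, 5, 21]
        for level in range(3):
            level_sum = pf.values[offsets[level] : offsets[level + 1]].sum()
            assert level_sum == 16 * 16

    def test_constant_word_concentrates_one_bin(self):
        hm = HashedMap(np.full((8, 8), 7), 0)
        pf = pyramid_histogram(hm, L=1)
        assert np.all(pf.values[:, 7] > 0)
        mask = np.ones(256, bool)
        mask[7] = False
        assert pf.values[:, mask].sum() == 0

    def test_uneven_cell_boundaries(self):
        # 5 rows at level 1 split as floor(5*r/2): [0,2,5) -> 2 and 3 rows
        hm = HashedMap(np.zeros((5, 4), dtype=int), 0)
        pf = pyramid_histogram(hm, L=1)
        counts = pf.values[1:].sum(axis=1)
        np.testing.assert_array_equal(counts, [2 * 2, 2 * 2, 3 * 2, 3 * 2])

    def test_excessive_depth_rejected(self):
        with pytest.raises(ValueError):
            pyramid_histogram(HashedMap(np.zeros((4, 4), dtype=int), 0), L=3)


class TestHighDispersal:
    def test_unit_norm_scales_to_sigma(self):
        vals = np.zeros((21, 256))
        vals[0, 0] = 1.0
        out = high_dispersal(PyramidFeature(vals, 0), sigma=2.238)
        assert np.linalg.norm(out.values) == pytest.approx(2.238)

    def test_all_zero_passes_through(self):
        out = high_dispersal(PyramidFeature(np.zeros((5, 256)), 0), sigma=2.238)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_random_feature_norm_is_sigma(self, rng):
        vals = rng.poisson(3.0, (21, 256)).astype(float)
        out = high_dispersal(PyramidFeature(vals, 0), sigma=2.238)
        # norm recomputed independently of the implementation's path
        indep = np.sqrt(sum(x * x for x in out.values.ravel().tolist()))
        assert indep == pytest.approx(2.238, abs=1e-9)

    def test_no_sqrt_variant_divides_by_sum_of_squares(self, rng):
        vals = rng.poisson(3.0, (4, 256)).astype(float)
        out = high_dispersal(PyramidFeature(vals, 0), sigma=2.0, sqrt_norm=False)
        np.testing.assert_allclose(out.values, 2.0 * vals / np.sum(vals**2))

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            high_dispersal(PyramidFeature(np.ones((2, 256)), 0), sigma=0.0)


class TestLocalResponseNormalize:
    def test_single_map_zero_stays_zero(self):
        out = local_response_normalize(
            [PyramidFeature(np.zeros((3, 256)), 0)], gamma=2.0, alpha=1e-4, beta=0.75, n_lrn=5
        )
        np.testing.assert_array_equal(out[0].values, 0.0)

    def test_scalar_worked_example(self):
        vals = np.zeros((1, 256))
        vals[0, 0] = 1.0
        out = local_response_normalize(
            [PyramidFeature(vals, 0)], gamma=2.0, alpha=1e-4, beta=0.75, n_lrn=5
        )
        assert out[0].values[0, 0] == pytest.approx(1.0 / (2.0 + 1e-4) ** 0.75, abs=1e-6)
        assert out[0].values[0, 0] == pytest.approx(0.59458, abs=1e-5)

    def test_alpha_zero_is_uniform_gamma_power(self, rng):
        pfs = [PyramidFeature(rng.uniform(0, 2, (3, 256)), j) for j in range(4)]
        out = local_response_normalize(pfs, gamma=2.0, alpha=0.0, beta=0.75, n_lrn=3)
        for pf_in, pf_out in zip(pfs, out):
            np.testing.assert_allclose(pf_out.values, pf_in.values / 2.0**0.75)

    def test_window_clipping_at_edges(self, rng):
        """Map 1's window with n=5 covers maps 1..3 (1-based), not 0 or -1."""
        pfs = [PyramidFeature(rng.uniform(0, 2, (2, 256)), j) for j in range(8)]
        out = local_response_normalize(pfs, gamma=2.0, alpha=0.1, beta=0.75, n_lrn=5)
        sq = np.stack([pf.values**2 for pf in pfs])
        expected_first = pfs[0].values / (2.0 + 0.1 * sq[0:3].sum(axis=0)) ** 0.75
        np.testing.assert_allclose(out[0].values, expected_first)
        expected_mid = pfs[4].values / (2.0 + 0.1 * sq[2:7].sum(axis=0)) ** 0.75
        np.testing.assert_allclose(out[4].values, expected_mid)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            local_response_normalize(
                [PyramidFeature(np.zeros((2, 256)), 0), PyramidFeature(np.zeros((3, 256)), 1)],
                gamma=2.0, alpha=1e-4, beta=0.75, n_lrn=5,
            )


class TestVectorize:
    def test_default_length_contract(self):
        assert feature_length(HyperParams()) == 43008

    def test_minimal_length(self):
        assert feature_length(HyperParams(V1=1, V2=1, s1=3, s2=3, L=0)) == 256

    def test_round_trip_deconcatenation(self, rng):
        pfs = [PyramidFeature(rng.uniform(size=(5, 256)), j) for j in range(3)]
        flat = vectorize(pfs)
        assert flat.shape == (3 * 5 * 256,)
        for j in range(3):
            np.testing.assert_array_equal(
                flat[j * 1280 : (j + 1) * 1280].reshape(5, 256), pfs[j].values
            )


class TestExtractFeatures:
    def test_ablated_baseline_length(self, tiny_net, tiny_images):
        imgs, _ = tiny_images
        hp = tiny_net.hp.with_ablation(use_nt=False, use_mfa=False, use_hd=False, use_lrn=False)
        feats = extract_features(imgs[:2], tiny_net.bank1, tiny_net.bank2, hp)
        assert feats.shape == (2, hp.V2 * 256)

    def test_deterministic_across_runs(self, tiny_net, tiny_images):
        imgs, _ = tiny_images
        a = tiny_net.transform(imgs[:2])
        b = tiny_net.transform(imgs[:2])
        np.testing.assert_array_equal(a, b)

    def test_constant_image_degenerate_path(self, tiny_net):
        """Constant input: interior responses vanish, hashing still yields a
        well-defined all-finite feature vector without error."""
        img = Image(np.full((16, 16), 60.0))
        feats = extract_features([img], tiny_net.bank1, tiny_net.bank2, tiny_net.hp)
        assert feats.shape == (1, feature_length(tiny_net.hp))
        assert np.all(np.isfinite(feats))

    def test_branch_permutation_preserves_cell_totals(self, rng):
        """Permuting stage-1 branches permutes word bit-planes but cannot
        change any cell's total pixel count."""
        binmaps = rng.integers(0, 2, (8, 16, 16))
        hm1 = rescale_hash(hash_group(binmaps))
        hm2 = rescale_hash(hash_group(binmaps[::-1]))
        pf1 = pyramid_histogram(hm1, L=2)
        pf2 = pyramid_histogram(hm2, L=2)
        np.testing.assert_array_equal(pf1.values.sum(axis=1), pf2.values.sum(axis=1))
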