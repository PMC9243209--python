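"""ULBPEZ feature extraction: grids, uniform mapping, LBP codes, zero-run coding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ulbpez as u
from ulbpez.features import (
    EncodedFeatureVector,
    LBPConfig,
    SUPPORTED_P,
    TABLE_CAPACITIES,
    _uniform_codes,
)


class TestGridFormulas:
    @pytest.mark.parametrize("R,block", [(2, 5), (3, 7), (4, 9), (5, 11)])
    def test_block_size(self, R, block):
        assert u.block_size_for(R) == block

    @pytest.mark.parametrize("R,div", [(2, 100), (3, 70), (4, 55), (5, 45)])
    def test_divisions_at_512(self, R, div):
        assert u.divisions_for(512, R) == div

    @pytest.mark.parametrize("P,bins", [(8, 59), (12, 135), (16, 243), (20, 383), (24, 555)])
    def test_bin_count(self, P, bins):
        assert u.n_bins_for(P) == bins

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            u.divisions_for(30, 3)

    @pytest.mark.parametrize("P", SUPPORTED_P)
    @pytest.mark.parametrize("R", [2, 3, 4, 5])
    def test_config_consistency(self, P, R):
        cfg = LBPConfig(P=P, R=R)
        assert cfg.n_bins == P * (P - 1) + 3
        assert cfg.divisions * cfg.block_size <= 512
        assert cfg.capacity == TABLE_CAPACITIES[R]


class TestUniformMapping:
    def test_transition_counts(self):
        assert u.circular_transitions(0b00000000, 8) == 0
        assert u.circular_transitions(0b00001111, 8) == 2
        assert u.circular_transitions(0b01010101, 8) == 8

    def test_p8_uniform_count_by_exhaustion(self):
        # independent oracle: count transitions over all 256 raw codes
        uniform = [c for c in range(256) if u.circular_transitions(c, 8) <= 2]
        assert len(uniform) == 58
        assert set(uniform) == set(_uniform_codes(8).tolist())

    def test_all_ones_code_is_last_uniform_bin(self):
        mapping = u.build_uniform_mapping(8)
        assert mapping[255] == 57
        assert mapping[0] == 0

    @pytest.mark.parametrize("P", SUPPORTED_P)
    def test_mapping_covers_exactly_the_bin_count(self, P):
        mapping = u.build_uniform_mapping(P)
        bins = set(mapping.lookup(mapping.uniform_codes).tolist())
        bins.add(mapping.nonuniform_bin)
        assert len(bins) == P * (P - 1) + 3
        assert max(bins) == P * (P - 1) + 2

    def test_nonuniform_codes_share_catchall(self):
        mapping = u.build_uniform_mapping(8)
        assert mapping[0b01010101] == 58
        assert mapping[0b00100101] == 58


def _brute_force_code_r1(img, row, col):
    """Independent 8-neighbour integer-threshold LBP at R=1.

    Neighbour k at angle 2*pi*k/8 counter-clockwise from east, so the
    integer offsets (drow, dcol) are E, NE, N, NW, W, SW, S, SE.
    """
    offs = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
    centre = int(img[row, col])
    code = 0
    for k, (dr, dc) in enumerate(offs):
        if int(img[row + dr, col + dc]) >= centre:
            code |= 1 << k
    return code


class TestLbpCode:
    def test_constant_patch_gives_all_ones(self):
        cfg = LBPConfig(P=8, R=3)
        img = np.full((16, 16), 99, np.uint8)
        assert u.lbp_code(img, 8, 8, cfg) == 255

    def test_bright_centre_gives_zero(self):
        cfg = LBPConfig(P=8, R=3)
        img = np.full((16, 16), 50, np.uint8)
        img[8, 8] = 200
        assert u.lbp_code(img, 8, 8, cfg) == 0

    def test_hand_patch_matches_manual_thresholding(self):
        cfg = LBPConfig(P=8, R=1, image_side=512, capacity=1)
        img = np.array([[5, 2, 8], [1, 4, 9], [3, 7, 6]], np.uint8)
        assert u.lbp_code(img, 1, 1, cfg) == _brute_force_code_r1(img, 1, 1)

    def test_out_of_bounds_rejected(self):
        cfg = LBPConfig(P=8, R=3)
        with pytest.raises(ValueError):
            u.lbp_code(np.zeros((16, 16), np.uint8), 1, 8, cfg)

    def test_agrees_with_brute_force_on_random_images(self):
        cfg = LBPConfig(P=8, R=1, image_side=512, capacity=1)
        rng = np.random.default_rng(11)
        for _ in range(5):
            img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
            for row in range(1, 15):
                for col in range(1, 15):
                    assert u.lbp_code(img, row, col, cfg) == _brute_force_code_r1(
                        img, row, col
                    ), (row, col)


class TestBlockHistogram:
    def test_single_contributor_sums_to_one(self):
        cfg = LBPConfig(P=8, R=3)
        mapping = u.build_uniform_mapping(8)
        rng = np.random.default_rng(12)
        img = rng.integers(0, 256, (14, 14)).astype(np.uint8)
        hist = u.block_histogram(img, (0, 0), cfg, mapping)
        assert hist.sum() == 1

    def test_constant_block_hits_all_ones_bin(self):
        cfg = LBPConfig(P=8, R=3)
        mapping = u.build_uniform_mapping(8)
        img = np.full((7, 7), 10, np.uint8)
        hist = u.block_histogram(img, (0, 0), cfg, mapping)
        assert hist[mapping[255]] == 1 and hist.sum() == 1

    def test_one_hot_position_matches_centre_code(self):
        cfg = LBPConfig(P=8, R=3)
        mapping = u.build_uniform_mapping(8)
        rng = np.random.default_rng(13)
        img = rng.integers(0, 256, (7, 7)).astype(np.uint8)
        hist = u.block_histogram(img, (0, 0), cfg, mapping)
        expected_bin = mapping[u.lbp_code(img, 3, 3, cfg)]
        assert hist[expected_bin] == 1


class TestStackFeatures:
    def test_full_mask_length_is_closed_form(self):
        cfg = LBPConfig(P=8, R=3)
        rng = np.random.default_rng(14)
        img = rng.integers(0, 256, (512, 512)).astype(np.uint8)
        stacked = u.stack_features(img, np.ones((512, 512), bool), cfg)
        assert len(stacked) == 70 * 70 * 59 == 289100
        assert stacked.n_blocks_used == 4900

    def test_every_block_is_one_hot(self):
        cfg = LBPConfig(P=8, R=3)
        rng = np.random.default_rng(15)
        img = rng.integers(0, 256, (512, 512)).astype(np.uint8)
        stacked = u.stack_features(img, np.ones((512, 512), bool), cfg)
        assert (stacked.values.reshape(-1, 59).sum(axis=1) == 1).all()

    def test_all_background_rejected(self):
        cfg = LBPConfig(P=8, R=3)
        with pytest.raises(ValueError):
            u.stack_features(
                np.zeros((512, 512), np.uint8), np.zeros((512, 512), bool), cfg
            )

    def test_mask_shrinking_never_grows_features(self):
        cfg = LBPConfig(P=8, R=3)
        rng = np.random.default_rng(16)
        img = rng.integers(0, 256, (512, 512)).astype(np.uint8)
        big = np.ones((512, 512), bool)
        small = big.copy()
        small[:100] = False
        assert len(u.stack_features(img, small, cfg)) <= len(
            u.stack_features(img, big, cfg)
        )

    def test_background_blocks_are_skipped_exactly(self):
        cfg = LBPConfig(P=8, R=3)
        rng = np.random.default_rng(17)
        img = rng.integers(0, 256, (512, 512)).astype(np.uint8)
        mask = np.ones((512, 512), bool)
        mask[0, 0] = False  # kills exactly the first block
        stacked = u.stack_features(img, mask, cfg)
        assert stacked.n_blocks_used == 4899


class TestZeroRunEncoding:
    def test_all_zero_vector(self):
        enc = u.encode_zeros(np.array([0, 0, 0, 0]))
        assert enc.tokens.tolist() == [4, 0]
        assert u.decode_zeros(enc).tolist() == [0, 0, 0, 0]

    def test_worked_example(self):
        enc = u.encode_zeros(np.array([5, 0, 0, 0, 2, 0, 1]))
        assert enc.tokens.tolist() == [0, 5, 3, 2, 1, 1, 0, 0]
        assert u.decode_zeros(enc).tolist() == [5, 0, 0, 0, 2, 0, 1]

    @settings(max_examples=1000, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.integers(min_value=0, max_value=9).filter(lambda v: True),
            min_size=1,
            max_size=200,
        )
    )
    def test_roundtrip_identity(self, values):
        vec = np.array(values, dtype=np.int64)
        assert (u.decode_zeros(u.encode_zeros(vec)) == vec).all()

    def test_roundtrip_on_long_sparse_vectors(self):
        rng = np.random.default_rng(18)
        for _ in range(20):
            vec = np.zeros(10_000, np.int64)
            idx = rng.choice(10_000, size=150, replace=False)
            vec[idx] = rng.integers(1, 100, size=150)
            assert (u.decode_zeros(u.encode_zeros(vec)) == vec).all()

    def test_capacity_overflow_raises(self):
        with pytest.raises(ValueError, match="capacity"):
            u.encode_zeros(np.array([1, 1, 1, 1]), capacity=4)

    def test_token_count_bound_for_one_hot_blocks(self, enhanced_and_mask):
        enhanced, mask = enhanced_and_mask
        cfg = LBPConfig(P=8, R=3)
        stacked = u.stack_features(enhanced, mask, cfg)
        enc = u.encode_zeros(stacked, cfg.capacity)
        assert enc.tokens.size <= 2 * stacked.n_blocks_used + 2


class TestPaddingAndFeatureImage:
    def test_pad_right_fills_zeros(self):
        enc = EncodedFeatureVector(
            tokens=np.arange(1, 9), original_length=100, capacity=8200
        )
        padded = u.pad_to_capacity(enc)
        assert padded.size == 8200
        assert (padded[:8] == np.arange(1, 9)).all()
        assert (padded[8:] == 0).all()

    @pytest.mark.parametrize("capacity,side", [(8200, 91), (3300, 58), (16150, 128), (4950, 71)])
    def test_feature_image_side(self, capacity, side):
        assert u.feature_image_side(capacity) == side

    def test_all_zero_vector_renders_black(self):
        img = u.to_feature_image(np.zeros(8200), 8200)
        assert img.shape == (91, 91) and not img.any()

    def test_values_in_byte_range(self):
        rng = np.random.default_rng(19)
        vec = rng.integers(0, 300, 8200)
        img = u.to_feature_image(vec, 8200)
        assert img.dtype == np.uint8 and img.shape == (91, 91)


class TestCompression:
    def test_encoded_fraction_below_five_percent(self, enhanced_and_mask):
        enhanced, mask = enhanced_and_mask
        cfg = LBPConfig(P=8, R=3)
        stacked = u.stack_features(enhanced, mask, cfg)
        enc = u.encode_zeros(stacked, cfg.capacity)
        assert enc.tokens.size / len(stacked) <= 0.05
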