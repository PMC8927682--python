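"""Preprocessing chain: gamma, green channel, CLAHE, masking, patching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselshot import preprocessing as pp
from vesselshot.exceptions import (ConsistencyError, ParameterError,
                                   ShapeError, SizeError)


class TestGammaCorrect:
    def test_identity_at_gamma_one(self, rng):
        plane = rng.uniform(0, 1, (8, 8, 3))
        image = pp.FundusImage(plane, "x")
        np.testing.assert_array_equal(pp.gamma_correct(image, 1.0).pixels,
                                      plane)

    def test_power_law_on_constant_image(self):
        image = pp.FundusImage(np.full((4, 4, 3), 0.25), "x")
        np.testing.assert_allclose(pp.gamma_correct(image, 2.0).pixels, 0.0625)

    def test_zero_is_a_fixed_point(self):
        image = pp.FundusImage(np.zeros((4, 4, 3)), "x")
        for gamma in (0.5, 1.2, 3.0):
            assert pp.gamma_correct(image, gamma).pixels.max() == 0.0

    def test_order_preserving_per_pixel(self, rng):
        a, b = np.sort(rng.uniform(0, 1, (2, 16)), axis=0)
        ga = pp.gamma_correct(a, 1.7)
        gb = pp.gamma_correct(b, 1.7)
        assert np.all(ga <= gb)

    def test_rejects_non_positive_gamma(self):
        with pytest.raises(ParameterError):
            pp.gamma_correct(np.zeros((4, 4)), 0.0)


class TestGreenChannel:
    def test_selects_channel_one(self):
        pixel = np.array([[[0.2, 0.7, 0.1]]])
        assert pp.green_channel(pixel) == pytest.approx(0.7)

    def test_gray_replicated_rgb_is_identity(self, rng):
        plane = rng.uniform(0, 1, (5, 5))
        rgb = np.stack([plane] * 3, axis=-1)
        np.testing.assert_array_equal(pp.green_channel(rgb), plane)

    def test_rejects_wrong_channel_count(self):
        with pytest.raises(ShapeError):
            pp.green_channel(np.zeros((4, 4)))


class TestClahe:
    def test_constant_plane_stays_constant(self):
        out = pp.clahe(np.full((64, 64), 0.5))
        assert np.unique(out).size == 1

    def test_does_not_shrink_two_value_separation(self):
        plane = np.full((64, 64), 0.4)
        plane[:, 32:] = 0.6
        out = pp.clahe(plane, clip_limit=4.0)
        gap_before = 0.2
        gap_after = out[:, 48].mean() - out[:, 16].mean()
        assert gap_after >= gap_before - 1e-9

    def test_range_contract_and_determinism(self, rng):
        plane = rng.uniform(0, 1, (64, 64))
        out1 = pp.clahe(plane)
        out2 = pp.clahe(plane)
        assert out1.min() >= 0 and out1.max() <= 1
        np.testing.assert_array_equal(out1, out2)

    def test_rejects_non_positive_clip_limit(self):
        with pytest.raises(ParameterError):
            pp.clahe(np.zeros((8, 8)), clip_limit=0.0)


class TestFieldMask:
    def test_all_ones_is_identity(self, rng):
        plane = rng.uniform(0, 1, (6, 6))
        fov = pp.BinaryMask(np.ones((6, 6), dtype=int), "field_of_view")
        np.testing.assert_array_equal(pp.apply_field_mask(plane, fov), plane)

    def test_all_zeros_blanks_the_plane(self, rng):
        plane = rng.uniform(0.1, 1, (6, 6))
        fov = pp.BinaryMask(np.zeros((6, 6), dtype=int), "field_of_view")
        assert pp.apply_field_mask(plane, fov).max() == 0.0

    def test_single_pixel_fov(self):
        plane = np.full((5, 5), 0.8)
        fov = np.zeros((5, 5), dtype=int)
        fov[2, 3] = 1
        out = pp.apply_field_mask(plane, pp.BinaryMask(fov, "field_of_view"))
        assert np.count_nonzero(out) == 1 and out[2, 3] == 0.8

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            pp.apply_field_mask(np.zeros((4, 4)),
                                pp.BinaryMask(np.zeros((5, 5), dtype=int),
                                              "field_of_view"))


def brute_force_origins(extent, template, stride):
    """Oracle: all stride-multiple top-left corners plus border-flush ones."""
    def axis(n):
        offs = [o for o in range(0, n - template + 1)
                if o % stride == 0]
        if offs[-1] != n - template:
            offs.append(n - template)
        return offs

    return [(r, c) for r in axis(extent[0]) for c in axis(extent[1])]


class TestPatchGrid:
    @pytest.mark.parametrize("extent,expected_axis", [
        ((224, 224), [0]),
        ((352, 352), [0, 64, 128]),
        ((300, 300), [0, 64, 76]),       # border-flush origin appended
        ((288, 352), [0, 64]),
    ])
    def test_origin_enumeration(self, extent, expected_axis):
        grid = pp.PatchGrid.for_extent(extent, template=224, stride=64)
        rows = sorted({o[0] for o in grid.origins})
        assert rows == expected_axis

    @pytest.mark.parametrize("extent", [(224, 224), (352, 352), (300, 317),
                                        (250, 401)])
    def test_matches_brute_force_oracle(self, extent):
        grid = pp.PatchGrid.for_extent(extent, template=224, stride=64)
        assert grid.origins == brute_force_origins(extent, 224, 64)

    def test_overlap_property(self):
        grid = pp.PatchGrid.for_extent((352, 352))
        assert grid.overlap == 160

    def test_full_coverage(self):
        grid = pp.PatchGrid.for_extent((300, 300), template=64, stride=48)
        cover = np.zeros((300, 300), dtype=int)
        for r, c in grid.origins:
            cover[r:r + 64, c:c + 64] += 1
        assert cover.min() >= 1

    def test_too_small_image(self):
        with pytest.raises(SizeError):
            pp.PatchGrid.for_extent((200, 224), template=224, stride=64)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(h=st.integers(64, 400), w=st.integers(64, 400),
           stride=st.integers(8, 96))
    def test_origins_match_oracle_for_arbitrary_extents(self, h, w, stride):
        grid = pp.PatchGrid.for_extent((h, w), template=64, stride=stride)
        assert grid.origins == brute_force_origins((h, w), 64, stride)


class TestExtractReassemble:
    def test_exact_fit_yields_single_patch(self, rng):
        plane = rng.uniform(0, 1, (224, 224))
        mask = (plane > 0.5).astype(np.uint8)
        grid = pp.PatchGrid.for_extent((224, 224))
        pairs = pp.extract_patches(plane, mask, grid)
        assert len(pairs) == 1
        np.testing.assert_array_equal(pairs[0][0], plane)
        np.testing.assert_array_equal(pairs[0][1], mask)

    def test_352_yields_nine_patches(self, rng):
        plane = rng.uniform(0, 1, (352, 352))
        grid = pp.PatchGrid.for_extent((352, 352))
        pairs = pp.extract_patches(plane, np.zeros_like(plane, dtype=np.uint8),
                                   grid)
        assert len(pairs) == 9

    def test_reassemble_round_trips(self, rng):
        plane = rng.uniform(0, 1, (300, 300))
        grid = pp.PatchGrid.for_extent((300, 300), template=64, stride=48)
        pairs = pp.extract_patches(plane, np.zeros_like(plane, dtype=np.uint8),
                                   grid)
        back = pp.reassemble([p for p, _ in pairs], grid, (300, 300))
        np.testing.assert_allclose(back, plane, atol=1e-6)

    def test_reassemble_averages_overlaps(self):
        grid = pp.PatchGrid(template=4, stride=4, origins=[(0, 0), (0, 0)])
        out = pp.reassemble([np.full((4, 4), 0.2), np.full((4, 4), 0.8)],
                            grid, (4, 4))
        np.testing.assert_allclose(out, 0.5)

    def test_reassemble_count_mismatch(self):
        grid = pp.PatchGrid.for_extent((224, 224))
        with pytest.raises(ConsistencyError):
            pp.reassemble([], grid, (224, 224))


def test_resize_mask_stays_binary(rng):
    mask = (rng.uniform(0, 1, (64, 64)) > 0.8).astype(np.uint8)
    small = pp.resize_mask(mask, (16, 16))
    assert set(np.unique(small)) <= {0.0, 1.0}


def test_full_chain_respects_fov(rng):
    image = pp.FundusImage(rng.uniform(0, 1, (64, 64, 3)), "x")
    fov = np.zeros((64, 64), dtype=int)
    fov[8:56, 8:56] = 1
    plane = pp.preprocess_image(image, pp.BinaryMask(fov, "field_of_view"))
    assert plane.shape == (64, 64)
    assert plane[fov == 0].max() == 0.0
    assert 0.0 <= plane.min() and plane.max() <= 1.0
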