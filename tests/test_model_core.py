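"""Architecture conformance, prototype math, guidance and attention."""

import numpy as np
import pytest

import vesselshot.autograd as ag
from vesselshot import model_core as mc
from vesselshot.exceptions import (ConfigurationError, ConsistencyError,
                                   ShapeError)
from vesselshot.model_core import FewShotSegmenter, ModelConfig


class TestMaskAveragePool:
    def test_hand_computed_two_by_two(self):
        feature = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        mask = np.array([[1, 0], [0, 1]])
        proto = mc.mask_average_pool(feature, mask)
        assert proto.vector[0] == pytest.approx((1 + 4) / 4)

    def test_full_mask_reduces_to_average_pooling(self, rng):
        feature = rng.uniform(-1, 1, (6, 6, 4))
        proto = mc.mask_average_pool(feature, np.ones((6, 6)))
        np.testing.assert_allclose(proto.vector, feature.mean(axis=(0, 1)))

    def test_empty_mask_gives_zero_vector(self, rng):
        feature = rng.uniform(-1, 1, (6, 6, 4))
        proto = mc.mask_average_pool(feature, np.zeros((6, 6)))
        np.testing.assert_array_equal(proto.vector, 0.0)

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(20):
            feature = rng.standard_normal((8, 8, 4))
            mask = (rng.uniform(0, 1, (8, 8)) > 0.5).astype(float)
            expected = np.zeros(4)
            for h in range(8):
                for w in range(8):
                    expected += feature[h, w] * mask[h, w]
            expected /= 64
            proto = mc.mask_average_pool(feature, mask)
            np.testing.assert_allclose(proto.vector, expected, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            mc.mask_average_pool(np.zeros((4, 4, 2)), np.zeros((5, 5)))


class TestCombineShots:
    def test_single_prototype_is_identity(self):
        p = mc.Prototype(np.array([1.0, 2.0]), position=3)
        np.testing.assert_array_equal(mc.combine_shots([p]).vector, p.vector)

    def test_mean_of_two(self):
        a = mc.Prototype(np.array([0.0, 2.0]))
        b = mc.Prototype(np.array([2.0, 0.0]))
        np.testing.assert_array_equal(mc.combine_shots([a, b]).vector,
                                      [1.0, 1.0])

    def test_mixed_positions_rejected(self):
        a = mc.Prototype(np.zeros(2), position=1)
        b = mc.Prototype(np.zeros(2), position=2)
        with pytest.raises(ConsistencyError):
            mc.combine_shots([a, b])


class TestPrototypeGuidance:
    def test_zero_prototype_gives_zero_grid(self, rng):
        grid = mc.prototype_guidance(np.zeros(3), rng.uniform(0, 1, (4, 4, 3)))
        np.testing.assert_array_equal(grid, 0.0)

    def test_one_hot_prototype_selects_channel(self, rng):
        feature = rng.uniform(0, 1, (5, 5, 3))
        grid = mc.prototype_guidance(np.array([0.0, 1.0, 0.0]), feature)
        np.testing.assert_allclose(grid, feature[:, :, 1])

    def test_matches_per_pixel_dot_product(self, rng):
        feature = rng.standard_normal((6, 7, 3))
        proto = rng.standard_normal(3)
        expected = np.einsum("hwc,c->hw", feature, proto)
        np.testing.assert_allclose(mc.prototype_guidance(proto, feature),
                                   expected, atol=1e-6)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            mc.prototype_guidance(np.zeros(4), np.zeros((4, 4, 3)))


class TestArchitecture:
    def test_reference_widths_match_table(self):
        model = FewShotSegmenter(ModelConfig(channel_scale=1.0), seed=0)
        assert tuple(model.encoder_widths()) == mc.ENCODER_WIDTHS
        assert tuple(model.decoder_widths()) == mc.DECODER_WIDTHS

    def test_feature_pyramid_sides(self, tiny_model):
        feats = tiny_model.encode(np.zeros((1, 224, 224)))
        assert [f.shape[2] for f in feats] == [224, 112, 56, 28, 14]
        feats = tiny_model.encode(np.zeros((1, 32, 32)))
        assert [f.shape[2] for f in feats] == [32, 16, 8, 4, 2]

    def test_side_not_divisible_by_16_rejected(self, tiny_model):
        with pytest.raises(ShapeError):
            tiny_model.encode(np.zeros((1, 60, 60)))

    def test_zero_input_zero_bias_gives_zero_maps(self):
        model = FewShotSegmenter(ModelConfig(channel_scale=0.0625), seed=3)
        feats = model.encode(np.zeros((1, 32, 32)))
        for f in feats:
            np.testing.assert_array_equal(f.data, 0.0)

    def test_channel_scale_floor_is_one(self):
        cfg = ModelConfig(channel_scale=0.01)
        assert cfg.scaled(64) >= 1

    def test_pretrained_flag_not_available(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(pretrained_encoder=True)


class TestMsaAttention:
    def test_constant_map_stays_constant_over_space(self, tiny_model):
        x = ag.Tensor(np.full((1, tiny_model.msa.channels, 4, 4), 0.3,
                              dtype=np.float32))
        out = tiny_model.msa(x).data
        for c in range(out.shape[1]):
            assert np.ptp(out[0, c]) < 1e-5

    def test_affinity_rows_sum_to_one(self, tiny_model, rng):
        x = ag.Tensor(rng.standard_normal(
            (2, tiny_model.msa.channels, 4, 4)).astype(np.float32))
        for block in tiny_model.msa.blocks:
            aff = block.affinity(x).data
            np.testing.assert_allclose(aff.sum(axis=-1), 1.0, atol=1e-5)

    def test_zero_projection_keeps_residual_identity(self, rng):
        import vesselshot.nn as nn
        block = nn.NonLocalBlock(4, np.random.default_rng(0))
        x = ag.Tensor(rng.standard_normal((1, 4, 3, 3)).astype(np.float32))
        np.testing.assert_allclose(block(x).data, x.data, atol=1e-6)

    def test_map_smaller_than_scale_rejected(self, tiny_model):
        x = ag.Tensor(np.zeros((1, tiny_model.msa.channels, 1, 1),
                               dtype=np.float32))
        with pytest.raises(ValueError):
            tiny_model.msa(x)


def episode_batch(rng, C=2, K=2, Q=2, side=32):
    sp = rng.uniform(0, 1, (C, K, side, side))
    sm = (rng.uniform(0, 1, (C, K, side, side)) > 0.8).astype(float)
    qp = rng.uniform(0, 1, (C, Q, side, side))
    return sp, sm, qp


class TestForwardPasses:
    def test_output_shape_and_range(self, tiny_model, tiny_baseline, rng):
        sp, sm, qp = episode_batch(rng)
        for model in (tiny_model, tiny_baseline):
            probs = model.episode_forward(sp, sm, qp).data
            assert probs.shape == (4, 1, 32, 32)
            assert probs.min() >= 0.0 and probs.max() <= 1.0
            assert np.all(np.isfinite(probs))

    def test_deterministic_given_fixed_weights(self, tiny_model, rng):
        sp, sm, qp = episode_batch(rng)
        a = tiny_model.episode_forward(sp, sm, qp).data
        b = tiny_model.episode_forward(sp, sm, qp).data
        np.testing.assert_array_equal(a, b)

    def test_zero_support_masks_zero_guidance(self, tiny_model, rng):
        sp, _, qp = episode_batch(rng)
        probs, internals = tiny_model.episode_forward(
            sp, np.zeros_like(sp), qp, return_internals=True)
        for grid in internals["guidance"].values():
            np.testing.assert_array_equal(grid.data, 0.0)
        for proto in internals["prototypes"].values():
            np.testing.assert_array_equal(proto.data, 0.0)

    def test_five_guidance_scales(self, tiny_model, rng):
        sp, sm, qp = episode_batch(rng, side=64)
        _, internals = tiny_model.episode_forward(sp, sm, qp,
                                                  return_internals=True)
        sides = {lv: g.shape[2] for lv, g in internals["guidance"].items()}
        assert sides == {1: 64, 2: 32, 3: 16, 4: 8, 5: 4}

    def test_baseline_uses_only_deepest_prototype(self, tiny_baseline, rng):
        sp, sm, qp = episode_batch(rng)
        _, internals = tiny_baseline.episode_forward(sp, sm, qp,
                                                     return_internals=True)
        assert set(internals["guidance"]) == {5}

    def test_support_shot_order_invariance(self, tiny_model, rng):
        sp, sm, qp = episode_batch(rng, K=3)
        perm = [2, 0, 1]
        a = tiny_model.episode_forward(sp, sm, qp).data
        b = tiny_model.episode_forward(sp[:, perm], sm[:, perm], qp).data
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_internal_prototypes_match_functional_route(self, tiny_model, rng):
        """The batched pipeline and the public numpy ops agree on the
        prototype of each class at every scale."""
        from vesselshot.preprocessing import resize_mask
        sp, sm, qp = episode_batch(rng, C=2, K=2)
        _, internals = tiny_model.episode_forward(sp, sm, qp,
                                                  return_internals=True)
        feats = tiny_model.encode(sp.reshape(4, 32, 32))
        for lv, proto in internals["prototypes"].items():
            fmap = feats[lv - 1].data  # (4, C_l, h, w)
            hl = fmap.shape[2]
            per_shot = []
            for i in range(4):
                mask_l = resize_mask(sm.reshape(4, 32, 32)[i], (hl, hl))
                per_shot.append(mc.mask_average_pool(
                    fmap[i].transpose(1, 2, 0), mask_l, position=lv))
            for c in range(2):
                merged = mc.combine_shots(per_shot[c * 2:(c + 1) * 2])
                np.testing.assert_allclose(proto.data[c], merged.vector,
                                           atol=1e-5)

    def test_ablation_hook_zeroes_upper_guidance(self, tiny_model, rng):
        sp, sm, qp = episode_batch(rng)
        _, internals = tiny_model.episode_forward(
            sp, sm, qp, zero_upper_guidance=True, return_internals=True)
        for lv, grid in internals["guidance"].items():
            if lv != 5:
                np.testing.assert_array_equal(grid.data, 0.0)
        assert np.abs(internals["guidance"][5].data).max() > 0


class TestCheckpoints:
    def test_round_trip_reproduces_outputs(self, tmp_path, rng):
        model = FewShotSegmenter(ModelConfig(channel_scale=0.0625), seed=7)
        sp, sm, qp = episode_batch(rng)
        before = model.episode_forward(sp, sm, qp).data
        path = tmp_path / "model.npz"
        mc.save_checkpoint(model, path, extra={"note": "test"})
        restored, meta = mc.load_checkpoint(path)
        after = restored.episode_forward(sp, sm, qp).data
        np.testing.assert_array_equal(before, after)
        assert meta["extra"]["note"] == "test"
        assert meta["config"]["channel_scale"] == 0.0625
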