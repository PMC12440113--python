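"""MAE-FUnet: backbone arithmetic, fusion contracts, segmentation losses."""
import numpy as np
import pytest

from maefunet import nn
from maefunet.funet import (
    FUnetConfig,
    FusionBlock,
    HybridLossConfig,
    MAEDirect,
    MAEFUnet,
    SegPrediction,
    UNet,
    ce_pixel_loss,
    dice_loss,
    focal_loss,
    hybrid_loss,
    train_segmenter,
)
from maefunet.mae import MAEModel, ViTConfig
from maefunet.nn import Tensor
from maefunet.volume_io import SliceSample


def _probs(logits):
    return Tensor(np.asarray(logits)).softmax(axis=1)


class TestConfig:
    def test_fusion_layer_count_must_be_depth_plus_one(self):
        with pytest.raises(ValueError, match="fusion layers"):
            FUnetConfig(num_classes=2, depth=2, fusion_layers=(1, 2), image_size=64)

    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            FUnetConfig(num_classes=1, depth=2, fusion_layers=(1, 2, 3), image_size=64)
        with pytest.raises(ValueError):
            FUnetConfig(num_classes=2, depth=2, fusion_layers=(1, 2, 3),
                        image_size=64, fusion_strategy="mystery")

    def test_fusion_layers_must_fit_encoder_depth(self, tiny_encoder):
        cfg = FUnetConfig(num_classes=2, depth=2, fusion_layers=(1, 2, 9), image_size=32)
        with pytest.raises(ValueError, match="encoder depth"):
            MAEFUnet(cfg, tiny_encoder)


class TestBackbone:
    def test_level_resolutions_halve_and_channels_double(self):
        cfg = FUnetConfig(num_classes=2, depth=2, base_dim=8,
                          fusion_layers=(1, 2, 3), image_size=32)
        unet = UNet(cfg, 0)
        assert unet.dims == [8, 16, 32]
        x = Tensor(np.random.default_rng(0).random((1, 1, 32, 32)))
        skips, bottom = unet.encode_cnn(x)
        assert [s.shape for s in skips] == [(1, 8, 32, 32), (1, 16, 16, 16)]
        assert bottom.shape == (1, 32, 8, 8)

    def test_full_scale_channel_progression(self):
        cfg = FUnetConfig(num_classes=2, depth=4, base_dim=64,
                          fusion_layers=(1, 3, 6, 9, 12), image_size=224)
        assert UNet(cfg, 0).dims == [64, 128, 256, 512, 1024]

    def test_parameter_count_increases_with_base_dim(self):
        counts = []
        for base in (8, 16, 24):
            cfg = FUnetConfig(num_classes=2, depth=2, base_dim=base,
                              fusion_layers=(1, 2, 3), image_size=32)
            counts.append(UNet(cfg, 0).n_parameters(trainable_only=True))
        assert counts[0] < counts[1] < counts[2]

    def test_forward_is_deterministic(self):
        cfg = FUnetConfig.tiny(image_size=32)
        unet = UNet(cfg, 0)
        img = np.random.default_rng(0).random((1, 32, 32))
        assert np.array_equal(unet(img).logits.data, unet(img).logits.data)

    def test_indivisible_input_rejected(self):
        cfg = FUnetConfig.tiny(image_size=64)
        with pytest.raises(ValueError, match="divisible"):
            UNet(cfg, 0)(np.zeros((1, 30, 30)))


class TestFusion:
    def _pair(self, c=8, hw=8):
        rng = np.random.default_rng(0)
        return (Tensor(rng.standard_normal((2, c, hw, hw))),
                Tensor(rng.standard_normal((2, c, hw, hw))))

    def test_add_with_zero_mae_features_is_identity(self):
        cnn, _ = self._pair()
        block = FusionBlock("add", 8, np.random.default_rng(0), gated=False)
        out = block(cnn, Tensor(np.zeros(cnn.shape)))
        assert np.array_equal(out.data, cnn.data)

    def test_gated_fusion_starts_as_identity_for_every_strategy(self):
        cnn, mae = self._pair()
        for strategy in ("concat", "add", "attention"):
            block = FusionBlock(strategy, 8, np.random.default_rng(1), gated=True)
            assert np.allclose(block(cnn, mae).data, cnn.data), strategy

    def test_all_strategies_return_cnn_shape(self):
        cnn, mae = self._pair()
        for strategy in ("concat", "add", "attention"):
            block = FusionBlock(strategy, 8, np.random.default_rng(2))
            assert block(cnn, mae).shape == cnn.shape

    def test_attention_with_uniform_keys_adds_query_independent_field(self):
        # constant keys/values make attention output independent of the query
        cnn, _ = self._pair(c=4, hw=4)
        block = FusionBlock("attention", 4, np.random.default_rng(3), gated=False)
        mae_const = Tensor(np.ones((2, 4, 4, 4)) * 0.5)
        out = block(cnn, mae_const)
        residual = out.data - cnn.data
        flat = residual.reshape(2, 4, -1)
        assert np.allclose(flat, flat[:, :, :1], atol=1e-10)

    def test_misaligned_shapes_rejected(self):
        cnn, _ = self._pair()
        block = FusionBlock("add", 8, np.random.default_rng(0))
        with pytest.raises(ValueError, match="aligned"):
            block(cnn, Tensor(np.zeros((2, 8, 4, 4))))

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            FusionBlock("mystery", 8, np.random.default_rng(0))


class TestTokenProjection:
    def test_tokens_reshape_to_grid_and_project(self, tiny_encoder):
        from maefunet.funet import TokenProjector

        proj = TokenProjector(32, 16, np.random.default_rng(0))
        tokens = Tensor(np.random.default_rng(0).standard_normal((2, 64, 32)))
        out = proj(tokens, grid=8, out_h=8, out_w=8)  # identity interpolation
        assert out.shape == (2, 16, 8, 8)
        out2 = proj(tokens, grid=8, out_h=16, out_w=16)
        assert out2.shape == (2, 16, 16, 16)
        with pytest.raises(ValueError):
            proj(tokens, grid=9, out_h=8, out_w=8)


@pytest.fixture(scope="module")
def seg_setup(tiny_encoder, brain_slices):
    cfg = FUnetConfig.tiny(image_size=32)
    samples = [s for s in brain_slices if s.brain_mask.mean() > 0.2][:6]
    for s in samples:
        s.label_grid = s.brain_mask.astype(np.int64)
    return cfg, samples


class TestSegmenters:
    @pytest.mark.parametrize("strategy", ["concat", "add", "attention"])
    def test_fused_output_matches_input_resolution(self, tiny_encoder, strategy):
        cfg = FUnetConfig.tiny(image_size=32, fusion_strategy=strategy)
        model = MAEFUnet(cfg, tiny_encoder, 0)
        img = np.random.default_rng(0).random((2, 32, 32))
        pred = model(img)
        assert pred.logits.shape == (2, 2, 32, 32)
        assert np.allclose(pred.probabilities.sum(axis=1), 1.0)
        assert pred.label_map.shape == (2, 32, 32)

    def test_strategies_are_drop_in_interchangeable(self, tiny_encoder):
        img = np.random.default_rng(1).random((1, 32, 32))
        shapes = set()
        for strategy in ("concat", "add", "attention"):
            cfg = FUnetConfig.tiny(image_size=32, fusion_strategy=strategy)
            shapes.add(MAEFUnet(cfg, tiny_encoder, 0)(img).logits.shape)
        assert len(shapes) == 1

    def test_mae_direct_outputs_full_resolution(self, tiny_encoder):
        model = MAEDirect(tiny_encoder, 2, 0)
        pred = model(np.random.default_rng(0).random((2, 32, 32)))
        assert pred.logits.shape == (2, 2, 32, 32)

    def test_encoder_digest_invariant_under_segmenter_training(
        self, tiny_encoder, seg_setup
    ):
        cfg, samples = seg_setup
        before = tiny_encoder.weight_digest()
        for strategy in ("concat", "add", "attention"):
            scfg = FUnetConfig.tiny(image_size=32, fusion_strategy=strategy)
            model = MAEFUnet(scfg, tiny_encoder, 0)
            train_segmenter(samples, model, seed=0, steps=3, batch_size=2)
            assert tiny_encoder.weight_digest() == before, strategy

    def test_training_is_deterministic_and_zero_steps_is_identity(
        self, tiny_encoder, seg_setup
    ):
        cfg, samples = seg_setup
        a = train_segmenter(samples, MAEFUnet(cfg, tiny_encoder, 1), seed=2, steps=3,
                            batch_size=2)
        b = train_segmenter(samples, MAEFUnet(cfg, tiny_encoder, 1), seed=2, steps=3,
                            batch_size=2)
        assert all(np.array_equal(a["state"][k], b["state"][k]) for k in a["state"])
        c = train_segmenter(samples, MAEFUnet(cfg, tiny_encoder, 1), seed=2, steps=0)
        ref = MAEFUnet(cfg, tiny_encoder, 1).state_dict()
        assert all(np.array_equal(c["state"][k], ref[k]) for k in ref)

    def test_loss_decreases_on_fixed_set(self, tiny_encoder, seg_setup):
        cfg, samples = seg_setup
        model = MAEFUnet(cfg, tiny_encoder, 0)
        ck = train_segmenter(samples, model, seed=0, steps=60, batch_size=6)
        assert np.mean(ck["loss_history"][-5:]) < ck["loss_history"][0]

    def test_out_of_range_labels_rejected(self, tiny_encoder, seg_setup):
        cfg, samples = seg_setup
        bad = [SliceSample(image=samples[0].image,
                           label_grid=np.full_like(samples[0].label_grid, 7))]
        with pytest.raises(ValueError, match="num_classes"):
            train_segmenter(bad, MAEFUnet(cfg, tiny_encoder, 0), steps=1)

    def test_tiny_model_overfits_one_labelled_slice(self, tiny_encoder, seg_setup):
        from maefunet.metrics import dice_score

        cfg, samples = seg_setup
        model = MAEFUnet(cfg, tiny_encoder, 0)
        one = samples[:1]
        train_segmenter(one, model, seed=0, steps=300, batch_size=1,
                        learning_rate=3e-3)
        pred = model(one[0].image[None]).label_map[0]
        assert dice_score(pred == 1, one[0].label_grid == 1) >= 0.99


class TestLosses:
    def test_dice_perfect_prediction_is_near_zero(self):
        g = np.array([[[0, 1], [1, 0]]])
        logits = np.zeros((1, 2, 2, 2))
        logits[0, 1] = np.where(g[0] == 1, 50.0, -50.0)
        logits[0, 0] = -logits[0, 1]
        assert dice_loss(_probs(logits), g).data < 1e-4

    def test_dice_empty_class_term_is_zero(self):
        # class 2 absent from prediction and truth: its term contributes 0
        g = np.zeros((1, 2, 2), dtype=int)
        logits = np.zeros((1, 3, 2, 2))
        logits[0, 0] = 50.0
        loss3 = dice_loss(_probs(logits), g).data
        # only background is matched perfectly; absent classes add nothing
        assert np.isclose(loss3, 0.0, atol=1e-4)

    def test_dice_matches_brute_force_on_4_pixel_grid(self):
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((1, 2, 2, 2))
        g = rng.integers(0, 2, (1, 2, 2))
        p = _probs(logits).data
        eps = 1e-5
        expect = 0.0
        for c in range(2):
            gc = (g[0] == c).astype(float)
            pc = p[0, c]
            expect += 1 - (2 * (pc * gc).sum() + eps) / ((pc**2).sum() + (gc**2).sum() + eps)
        expect /= 2
        assert np.allclose(dice_loss(_probs(logits), g).data, expect)

    def test_focal_closed_form_at_half_probability(self):
        # single pixel, p=0.5, gamma=2, alpha=0.25 -> 0.25 * 0.25 * ln 2
        logits = np.zeros((1, 2, 1, 1))
        g = np.zeros((1, 1, 1), dtype=int)
        out = focal_loss(_probs(logits), g, gamma=2.0, alpha=0.25)
        assert np.allclose(out.data, 0.25 * 0.25 * np.log(2), rtol=1e-12)

    def test_focal_vanishes_for_certain_predictions(self):
        g = np.zeros((1, 2, 2), dtype=int)
        logits = np.zeros((1, 2, 2, 2))
        logits[0, 0] = 80.0
        assert focal_loss(_probs(logits), g).data < 1e-12

    def test_focal_gamma0_alpha1_reduces_to_cross_entropy(self):
        rng = np.random.default_rng(2)
        logits = rng.standard_normal((2, 3, 4, 4)) * 3
        g = rng.integers(0, 3, (2, 4, 4))
        f = focal_loss(_probs(logits), g, gamma=0.0, alpha=1.0).data
        ce = ce_pixel_loss(Tensor(logits), g).data
        assert np.allclose(f, ce)

    def test_ce_uniform_prediction_gives_ln_c(self):
        for c in (2, 4, 9):
            logits = np.zeros((1, c, 3, 3))
            g = np.random.default_rng(c).integers(0, c, (1, 3, 3))
            assert np.allclose(ce_pixel_loss(Tensor(logits), g).data, np.log(c))

    def test_ce_equals_neg_log_softmax_oracle_on_random_instances(self):
        from scipy.special import log_softmax

        rng = np.random.default_rng(3)
        for _ in range(5):
            logits = rng.standard_normal((2, 4, 8, 8)) * 4
            g = rng.integers(0, 4, (2, 8, 8))
            oracle = -np.take_along_axis(
                log_softmax(logits, axis=1), g[:, None], axis=1
            ).mean()
            assert np.allclose(ce_pixel_loss(Tensor(logits), g).data, oracle)

    def test_hybrid_is_weighted_sum_of_components(self):
        rng = np.random.default_rng(4)
        logits = rng.standard_normal((1, 2, 2, 2))
        g = rng.integers(0, 2, (1, 2, 2))
        cfg = HybridLossConfig()
        p = _probs(logits)
        expect = (
            dice_loss(p, g, cfg.eps).data
            + focal_loss(p, g, cfg.gamma, cfg.alpha).data
            + ce_pixel_loss(Tensor(logits), g).data
        )
        assert np.allclose(hybrid_loss(Tensor(logits), g, cfg).data, expect)

    def test_hybrid_component_isolation_and_zero_weights(self):
        rng = np.random.default_rng(5)
        logits = rng.standard_normal((1, 3, 4, 4))
        g = rng.integers(0, 3, (1, 4, 4))
        zero = hybrid_loss(Tensor(logits), g,
                           HybridLossConfig(lambda_dice=0, lambda_focal=0, lambda_ce=0))
        assert zero.data == 0.0
        only_dice = hybrid_loss(Tensor(logits), g,
                                HybridLossConfig(lambda_focal=0, lambda_ce=0))
        assert np.allclose(only_dice.data, dice_loss(_probs(logits), g).data)

    def test_hybrid_loss_is_nonnegative_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            logits = rng.standard_normal((1, 3, 4, 4)) * 5
            g = rng.integers(0, 3, (1, 4, 4))
            assert hybrid_loss(Tensor(logits), g).data >= -1e-6
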