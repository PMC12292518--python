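"""Segmenter components: loss, preprocessing, temporal windows, network."""

import numpy as np
import pytest

from spinetrack import (
    KinematicsConfig,
    ModelConfig,
    NormalizationStats,
    augment,
    build_unet,
    class_weights,
    make_recording,
    make_temporal_input,
    normalize,
    predict,
    predicted_frame_indices,
    weighted_dice_loss,
)
from spinetrack import unet as unet_mod
from spinetrack.synthetic import Recording


class TestClassWeights:
    def test_hand_values(self):
        gt = np.zeros((2, 4, 4))
        gt[0, 0, :4] = 1  # 4 foreground pixels -> W = 1/16
        gt[1, 0, 0] = 1  # 1 foreground pixel -> W = 1
        w = class_weights(gt)
        assert w[0] == pytest.approx(1 / 16)
        assert w[1] == pytest.approx(1.0)

    def test_empty_class_weight_zero(self, caplog):
        import logging

        gt = np.zeros((2, 3, 3))
        gt[0, 0, 0] = 1
        with caplog.at_level(logging.WARNING, logger="spinetrack.unet"):
            w = class_weights(gt)
        assert w[1] == 0.0
        assert "weight 0" in caplog.text


class TestWeightedDiceLoss:
    def test_perfect_prediction_zero(self):
        gt = np.zeros((3, 8, 8))
        gt[0, :4] = 1
        gt[1, 4:] = 1
        gt[2] = 0
        w = class_weights(gt)
        assert weighted_dice_loss(gt, gt, w) == pytest.approx(0.0)

    def test_empty_prediction_one(self):
        gt = np.zeros((1, 4, 4))
        gt[0, 1:3, 1:3] = 1
        assert weighted_dice_loss(np.zeros_like(gt), gt, class_weights(gt)) == pytest.approx(1.0)

    def test_hand_example_one_third(self):
        # N=4 pixels, gt=[1,1,0,0], p=[.5,.5,.5,.5] -> L = 1 - 2*1/(1+2) = 1/3
        gt = np.array([[1.0, 1.0, 0.0, 0.0]])
        p = np.full((1, 4), 0.5)
        assert weighted_dice_loss(p, gt, np.array([1.0])) == pytest.approx(1 / 3)

    def test_bounds_and_shape_error(self, rng):
        p = rng.uniform(size=(3, 6, 6))
        gt = (rng.uniform(size=(3, 6, 6)) > 0.5).astype(float)
        gt[0, 0, 0] = 1  # keep all classes populated
        w = class_weights(gt)
        loss = weighted_dice_loss(p, gt, w)
        assert 0.0 <= loss <= 1.0
        with pytest.raises(ValueError):
            weighted_dice_loss(p[:, :3], gt, w)

    def test_grad_matches_loss(self, rng):
        """Analytic gradient of the loss agrees with finite differences."""
        probs = rng.uniform(0.1, 0.9, size=(1, 2, 4, 4)).astype(np.float64)
        gt = (rng.uniform(size=(1, 2, 4, 4)) > 0.6).astype(np.float64)
        gt[0, :, 0, 0] = [1, 0]
        w = class_weights(gt.transpose(1, 0, 2, 3))
        _, grad = unet_mod._dice_loss_and_grad(probs, gt, w)
        eps = 1e-6
        for idx in [(0, 0, 1, 2), (0, 1, 3, 3)]:
            pp = probs.copy()
            pp[idx] += eps
            lp = weighted_dice_loss(pp.transpose(1, 0, 2, 3), gt.transpose(1, 0, 2, 3), w)
            pm = probs.copy()
            pm[idx] -= eps
            lm = weighted_dice_loss(pm.transpose(1, 0, 2, 3), gt.transpose(1, 0, 2, 3), w)
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-3, abs=1e-9)


class TestPreprocessing:
    def test_normalize_arithmetic(self):
        stats = NormalizationStats(mean=10.0, sd=2.0)
        out = normalize(np.array([[14.0]]), stats)
        assert out[0, 0] == pytest.approx(2.0)
        assert normalize(np.full((3, 3), 10.0), stats) == pytest.approx(0.0)
        ident = normalize(np.arange(4.0), NormalizationStats(0.0, 1.0))
        np.testing.assert_allclose(ident, np.arange(4.0))

    def test_normalize_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            NormalizationStats(mean=0.0, sd=0.0)
        with pytest.raises(ValueError):
            unet_mod.compute_normalization_stats(np.full((2, 4, 4), 3.0))

    def test_augment_identity_and_determinism(self, rng):
        frame = rng.uniform(size=(32, 32)).astype(np.float32)
        out = augment(frame, seed=0, noise_sd=0.0, contrast_range=(1.0, 1.0))
        np.testing.assert_allclose(out, frame, atol=1e-6)
        a = augment(frame, seed=5, noise_sd=0.05)
        b = augment(frame, seed=5, noise_sd=0.05)
        np.testing.assert_array_equal(a, b)

    def test_augment_noise_sd_realized(self, rng):
        frame = rng.uniform(size=(256, 256)).astype(np.float32)
        out = augment(frame, seed=1, noise_sd=0.1, contrast_range=(1.0, 1.0))
        assert (out - frame).std() == pytest.approx(0.1, rel=0.1)


class TestTemporalInput:
    @staticmethod
    def _rec(T=52):
        frames = np.arange(T, dtype=np.float32)[:, None, None] * np.ones((1, 8, 8), np.float32)
        return Recording(frames=frames, frame_rate=15.0, direction="extension", id="t")

    def test_k3_interior(self):
        rec = self._rec(10)
        x = make_temporal_input(rec, 4, 3)
        np.testing.assert_allclose(x[:, 0, 0], [3, 4, 5])

    def test_k1_reduction(self):
        rec = self._rec(10)
        x = make_temporal_input(rec, 7, 1)
        assert x.shape == (1, 8, 8)
        assert x[0, 0, 0] == 7

    def test_boundary_sentinel_and_counts(self):
        rec = self._rec(52)
        assert make_temporal_input(rec, 0, 7) is None
        assert make_temporal_input(rec, 2, 7) is None
        assert make_temporal_input(rec, 3, 7) is not None
        frames = predicted_frame_indices(52, 7)
        assert frames == list(range(3, 49))
        assert len(frames) == 46


class TestUNet:
    CFG = dict(n_levels=2, base_filters=4, image_size=(16, 16), seed=0)

    def test_softmax_output(self, rng):
        model = build_unet(ModelConfig(in_frames=1, **self.CFG))
        x = rng.normal(size=(2, 1, 16, 16)).astype(np.float32)
        probs = model.forward(x)
        assert probs.shape == (2, 9, 16, 16)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_seeded_init_deterministic(self):
        a = build_unet(ModelConfig(in_frames=1, **self.CFG))
        b = build_unet(ModelConfig(in_frames=1, **self.CFG))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_k_only_changes_first_layer(self):
        a = build_unet(ModelConfig(in_frames=1, **self.CFG))
        b = build_unet(ModelConfig(in_frames=7, **self.CFG))
        assert a.params["enc0a_W"].shape[1] == 1
        assert b.params["enc0a_W"].shape[1] == 7
        assert {k: v.shape for k, v in a.params.items() if k != "enc0a_W"} == {
            k: v.shape for k, v in b.params.items() if k != "enc0a_W"
        }

    def test_bad_image_size_rejected(self):
        with pytest.raises(ValueError):
            build_unet(ModelConfig(n_levels=5, image_size=(100, 100)))
        with pytest.raises(ValueError):
            build_unet(ModelConfig(in_frames=2))


def _tiny_dataset(seed=0):
    cfg = KinematicsConfig(
        seed=seed,
        n_frames=6,
        total_rom_deg=8.0,
        segment_amplitudes_deg={"C4-C5": 2.0},
        segment_peak_order=("C4-C5",),
        image_size=(64, 64),
        vertebra_height_px=5.5,
        spacing_px=7.0,
        noise_sd=0.01,
        occlusion_strength=0.0,
    )
    return make_recording(cfg)


class TestTraining:
    def test_loss_decreases_and_deterministic(self):
        rec, ann = _tiny_dataset()
        samples = unet_mod.build_training_samples([(rec, ann)], k=1)
        mcfg = ModelConfig(
            n_levels=2,
            in_frames=1,
            base_filters=4,
            image_size=(64, 64),
            learning_rate=1e-3,
            batch_size=4,
            max_epochs=8,
            patience=100,
            seed=0,
        )
        hist1 = unet_mod.train(build_unet(mcfg), samples, samples[:2])
        hist2 = unet_mod.train(build_unet(mcfg), samples, samples[:2])
        assert hist1["train_loss"][-1] < hist1["train_loss"][0]
        assert hist1["train_loss"] == hist2["train_loss"]
        assert hist1["val_loss"] == hist2["val_loss"]

    def test_normalization_stats_from_training_subset_only(self):
        """No information leak: stats match the training inputs exactly."""
        rec, ann = _tiny_dataset(0)
        rec2, ann2 = _tiny_dataset(1)
        train_s = unet_mod.build_training_samples([(rec, ann)], k=1)
        val_s = unet_mod.build_training_samples([(rec2, ann2)], k=1)
        mcfg = ModelConfig(
            n_levels=2, in_frames=1, base_filters=4, image_size=(64, 64),
            max_epochs=1, seed=0,
        )
        hist = unet_mod.train(build_unet(mcfg), train_s, val_s)
        expected = unet_mod.compute_normalization_stats(
            np.concatenate([x.reshape(-1) for x, _ in train_s])
        )
        assert hist["stats"] == expected

    def test_predict_counts_and_range(self):
        rec, ann = _tiny_dataset()
        stats = NormalizationStats(mean=0.4, sd=0.2)
        for k, expected in [(1, 6), (3, 4)]:
            mcfg = ModelConfig(
                n_levels=2, in_frames=k, base_filters=4, image_size=(64, 64), seed=0
            )
            model = build_unet(mcfg)
            probs = predict(model, rec, stats)
            assert len(probs.frames) == expected
            assert probs.maps.shape == (expected, 9, 64, 64)
            assert probs.maps.min() >= 0.0 and probs.maps.max() <= 1.0

    def test_predict_size_mismatch(self):
        rec, _ = _tiny_dataset()
        model = build_unet(
            ModelConfig(n_levels=2, in_frames=1, base_filters=4, image_size=(32, 32), seed=0)
        )
        with pytest.raises(ValueError):
            predict(model, rec, NormalizationStats(0.4, 0.2))
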