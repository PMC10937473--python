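"""Network kernel, masked loss, augmentation, LR schedule and training loop."""

import numpy as np
import pytest

from echolv.annotation import Dataset
from echolv.heatmap import decode_heatmap, encode_keypoints
from echolv.model import (
    AffineRanges,
    NetConfig,
    PlateauScheduler,
    TrainConfig,
    augment_pair,
    masked_mse,
    masked_mse_grad,
    predict_keypoints,
    train,
)
from echolv.nn import UNet
from echolv.phantom import PhantomSpec, generate_cohort


TINY64_RANGES = {
    "axis_origin_x": (28.0, 36.0),
    "axis_origin_y": (10.0, 14.0),
    "axis_angle": (np.pi / 2 - 0.1, np.pi / 2 + 0.1),
    "ivs_cm": (0.14, 0.19),
    "lvd_cm": (0.45, 0.60),
    "fw_cm": (0.14, 0.19),
    "wall_brightness": (0.8, 0.9),
    "chamber_brightness": (0.15, 0.25),
    "speckle_strength": (0.0, 0.0),
    "gamma": (1.0, 1.0),
    "sector_half_angle": (0.5, 0.6),
}
BASE64 = PhantomSpec(size_px=64, spacing_cm_per_px=0.02)


class TestMaskedMse:
    def test_zero_when_equal(self):
        x = np.random.default_rng(0).uniform(size=(5, 8, 8))
        assert masked_mse(x, x, np.ones(5)) == 0.0

    def test_constant_difference_single_channel(self):
        pred = np.zeros((5, 8, 8))
        target = np.zeros((5, 8, 8))
        pred[2] += 0.1
        mask = np.zeros(5)
        mask[2] = 1
        assert masked_mse(pred, target, mask) == pytest.approx(0.01)

    def test_masked_channel_contributes_nothing(self):
        pred = np.zeros((5, 8, 8))
        target = np.zeros((5, 8, 8))
        pred[1] += 0.7  # difference lives only on a masked channel
        mask = np.ones(5)
        mask[1] = 0
        assert masked_mse(pred, target, mask) == 0.0

    def test_all_masked_returns_zero(self):
        pred = np.ones((5, 4, 4))
        assert masked_mse(pred, np.zeros_like(pred), np.zeros(5)) == 0.0

    def test_pseudo_line_weight_scales_its_term(self):
        pred = np.zeros((5, 4, 4))
        target = np.zeros((5, 4, 4))
        pred[4] += 0.1
        mask = np.zeros(5)
        mask[4] = 1
        full = masked_mse(pred, target, mask, pseudo_line_weight=1.0)
        half = masked_mse(pred, target, mask, pseudo_line_weight=0.5)
        assert half == pytest.approx(full / 2)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        pred = rng.uniform(size=(5, 6, 6))
        target = rng.uniform(size=(5, 6, 6))
        mask = np.array([1, 1, 0, 1, 1], float)
        g = masked_mse_grad(pred, target, mask, 0.7)
        eps = 1e-6
        for idx in [(0, 2, 3), (2, 1, 1), (4, 5, 0)]:
            p = pred.copy()
            p[idx] += eps
            lp = masked_mse(p, target, mask, 0.7)
            p[idx] -= 2 * eps
            lm = masked_mse(p, target, mask, 0.7)
            num = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(num, abs=1e-8)


class TestUNetKernel:
    def test_backprop_matches_numeric_gradient(self):
        net = UNet(depth=1, base_channels=2, in_channels=3, out_channels=5, seed=0)
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (1, 8, 8, 3)).astype(np.float32)
        target = rng.uniform(0, 1, (1, 5, 8, 8))
        mask = np.array([[1, 1, 0, 1, 1]], float)

        def loss():
            return masked_mse(net.forward(x).transpose(0, 3, 1, 2), target, mask)

        g = masked_mse_grad(net.forward(x).transpose(0, 3, 1, 2), target, mask)
        net.backward(g.transpose(0, 2, 3, 1).astype(np.float32))
        check_rng = np.random.default_rng(1)
        for p, grad in net.tensors():
            flat, gflat = p.reshape(-1), grad.reshape(-1)
            for idx in check_rng.choice(flat.size, size=min(3, flat.size),
                                        replace=False):
                eps = 1e-3
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                scale = max(abs(num), abs(gflat[idx]), 1e-6)
                assert abs(num - gflat[idx]) / scale < 1e-3

    def test_zero_initialised_head_outputs_zero(self):
        net = UNet(depth=2, base_channels=4, in_channels=3, out_channels=5, seed=3)
        x = np.random.default_rng(0).uniform(0, 1, (1, 16, 16, 3)).astype(np.float32)
        assert np.all(net.forward(x) == 0.0)

    def test_indivisible_input_rejected(self):
        net = UNet(depth=3, base_channels=2, in_channels=3, out_channels=5)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 20, 20, 3), dtype=np.float32))

    def test_weight_round_trip(self):
        net = UNet(depth=1, base_channels=2, in_channels=3, out_channels=5, seed=0)
        w = net.get_weights()
        other = UNet(depth=1, base_channels=2, in_channels=3, out_channels=5, seed=9)
        other.set_weights(w)
        x = np.random.default_rng(2).uniform(size=(1, 8, 8, 3)).astype(np.float32)
        assert np.array_equal(net.forward(x), other.forward(x))


class TestPlateauScheduler:
    def test_constant_loss_sequence_reduces_once_at_21(self):
        sched = PlateauScheduler(0.001, factor=5.0, patience=20)
        lrs = [sched.update(1.0) for _ in range(21)]
        assert lrs[19] == pytest.approx(0.001)
        assert lrs[20] == pytest.approx(0.0002)
        assert sched.bad_epochs == 0

    def test_hand_simulated_trace(self):
        # improvements reset the counter; two plateaus give two reductions
        sched = PlateauScheduler(1.0, factor=2.0, patience=2)
        trace = [5.0, 4.0, 4.5, 4.2,   # improve, improve, bad, bad -> /2
                 3.0,                  # improve (best 3.0)
                 3.5, 3.1,             # bad, bad -> /2
                 2.9]                  # improve
        lrs = [sched.update(v) for v in trace]
        assert lrs == pytest.approx([1.0, 1.0, 1.0, 0.5, 0.5, 0.5, 0.25, 0.25])


class TestAugmentPair:
    def _sample(self):
        ds, imgs = generate_cohort(1, TINY64_RANGES, seed=0, base_spec=BASE64)
        frame = ds.frames[0]
        ann = ds.annotations[0]
        from echolv.model import prepare_image
        img = prepare_image(imgs[frame.frame_id], (64, 64))
        stack = encode_keypoints(ann, frame, (64, 64), 4.0)
        return img, stack

    def test_identity_ranges_are_a_no_op(self):
        img, stack = self._sample()
        cfg = TrainConfig(augmentation=AffineRanges.identity())
        img2, stack2 = augment_pair(img, stack, cfg, seed=1)
        assert np.array_equal(img, img2)
        assert np.array_equal(stack.planes, stack2.planes)

    def test_pure_translation_shifts_decoded_peaks(self):
        img, stack = self._sample()
        cfg = TrainConfig(augmentation=AffineRanges(
            rotation_deg=0.0, translation_frac=5.0 / 64, scale_min=1.0,
            scale_max=1.0, gamma_min=1.0, gamma_max=1.0))
        from echolv.model import sample_affine
        angle, scale, (tx, ty), gamma = sample_affine(cfg.augmentation, (64, 64), 123)
        assert angle == 0.0 and scale == 1.0 and gamma == 1.0
        _, stack2 = augment_pair(img, stack, cfg, seed=123)
        for ch in range(4):
            x0, y0, _ = decode_heatmap(stack.planes[ch], confidence_floor=0.5)
            d = decode_heatmap(stack2.planes[ch], confidence_floor=0.5)
            assert d is not None
            assert d[0] - x0 == pytest.approx(tx, abs=0.5)
            assert d[1] - y0 == pytest.approx(ty, abs=0.5)

    def test_gamma_two_squares_a_constant_image(self):
        img = np.full((32, 32, 3), 0.5, dtype=np.float32)
        from echolv.heatmap import HeatmapStack
        stack = HeatmapStack(planes=np.zeros((5, 32, 32), np.float32), sigma_px=4.0,
                             loss_mask=np.zeros(5), scale_to_native=(1.0, 1.0))
        cfg = TrainConfig(augmentation=AffineRanges(
            rotation_deg=0.0, translation_frac=0.0, scale_min=1.0, scale_max=1.0,
            gamma_min=2.0, gamma_max=2.0))
        img2, _ = augment_pair(img, stack, cfg, seed=0)
        assert img2 == pytest.approx(np.full_like(img, 0.25), abs=1e-6)

    def test_masks_unchanged(self):
        img, stack = self._sample()
        cfg = TrainConfig()
        _, stack2 = augment_pair(img, stack, cfg, seed=5)
        assert np.array_equal(stack.loss_mask, stack2.loss_mask)


def _train_tiny(epochs=4, seed=0, n=24, optimizer="ADAM"):
    ds, imgs = generate_cohort(n, TINY64_RANGES, seed=seed, base_spec=BASE64)
    from echolv.annotation import split_dataset
    tr, te = split_dataset(ds, 0.75, seed=seed)
    netc = NetConfig(depth=1, base_channels=4, working_size=(64, 64))
    cfg = TrainConfig(epochs=epochs, batch_size=4, seed=seed, sigma_px=4.0,
                      augment=False, optimizer=optimizer)
    model = train(tr, te, imgs, netc, cfg)
    return model, te, imgs, cfg


class TestTraining:
    def test_loss_beats_all_zero_baseline(self):
        model, te, imgs, cfg = _train_tiny(epochs=4)
        # baseline: predicting all-zero heatmaps
        from echolv.model import _build_samples
        samples = _build_samples(te, imgs, model.net_config, cfg)
        base = np.mean([masked_mse(np.zeros_like(s.planes), s.planes, s.loss_mask)
                        for _, s in samples])
        best = min(h["test_loss"] for h in model.history)
        assert best < base

    def test_history_is_seed_deterministic(self):
        m1, *_ = _train_tiny(epochs=2, seed=3, n=8)
        m2, *_ = _train_tiny(epochs=2, seed=3, n=8)
        assert m1.history == m2.history

    def test_empty_dataset_rejected(self):
        ds, imgs = generate_cohort(4, TINY64_RANGES, seed=0, base_spec=BASE64)
        with pytest.raises(ValueError, match="non-empty"):
            train(ds, Dataset(), imgs, NetConfig(working_size=(64, 64)),
                  TrainConfig())

    def test_overlapping_datasets_rejected(self):
        ds, imgs = generate_cohort(4, TINY64_RANGES, seed=0, base_spec=BASE64)
        with pytest.raises(ValueError, match="overlap"):
            train(ds, ds, imgs, NetConfig(working_size=(64, 64)), TrainConfig())


class TestPredictKeypoints:
    def test_untrained_model_reports_all_none(self):
        from echolv.model import KeypointModel
        netc = NetConfig(depth=1, base_channels=2, working_size=(64, 64))
        model = KeypointModel(net=UNet(1, 2, 3, 5, seed=0), net_config=netc,
                              train_config=TrainConfig())
        ds, imgs = generate_cohort(1, TINY64_RANGES, seed=0, base_spec=BASE64)
        preds = predict_keypoints(model, ds.frames[0], imgs[ds.frames[0].frame_id])
        assert all(v is None for v in preds.values())

    def test_outputs_within_native_bounds(self):
        model, te, imgs, _ = _train_tiny(epochs=4)
        for frame in te.frames:
            preds = predict_keypoints(model, frame, imgs[frame.frame_id])
            for v in preds.values():
                if v is not None:
                    assert 0 <= v[0] < frame.width_px
                    assert 0 <= v[1] < frame.height_px
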