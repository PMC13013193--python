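"""Loss, normalization, augmentation, folds and the training loop."""

import numpy as np
import pytest

from nigraseg.nn import autodiff as ad
from nigraseg.nn.unet import NetConfig, build_unet3d
from nigraseg.training import (Adam, TrainConfig, asymmetric_loss,
                               augment_rotation, make_folds,
                               normalize_intensity, train)
from nigraseg.volume import ImageVolume


class TestAsymmetricLoss:
    def test_perfect_prediction_near_zero(self):
        y = (np.random.default_rng(0).random((4, 4, 4)) > 0.7).astype(
            np.float32)
        assert asymmetric_loss(y, y) <= 1e-5

    def test_all_background_prediction_near_one(self):
        y = np.ones((4, 4, 4), np.float32)
        assert asymmetric_loss(np.zeros_like(y), y) == pytest.approx(1.0,
                                                                     abs=1e-5)

    def test_hand_value_beta_1_5(self):
        # hard counts TP=2, FN=2, FP=0 with beta^2=2.25:
        # F = 3.25*2 / (3.25*2 + 2.25*2) = 6.5/11, loss = 1 - 6.5/11
        pred = np.array([1.0, 1.0, 0.0, 0.0], np.float32)
        truth = np.array([1.0, 1.0, 1.0, 1.0], np.float32)
        loss = asymmetric_loss(pred[None], truth[None], beta=1.5)
        assert loss == pytest.approx(1 - 6.5 / 11, abs=1e-5)
        assert loss == pytest.approx(0.40909, abs=1e-4)

    def test_beta_one_equals_soft_dice(self):
        rng = np.random.default_rng(1)
        pred = rng.random((2, 5, 5, 5)).astype(np.float32)
        truth = (rng.random((2, 5, 5, 5)) > 0.6).astype(np.float32)
        eps = 1e-6
        per_sample = []
        for p, t in zip(pred, truth):
            soft_dice = (2 * (p * t).sum() + eps) / (p.sum() + t.sum() + eps)
            per_sample.append(1 - soft_dice)
        assert asymmetric_loss(pred, truth, beta=1.0) == pytest.approx(
            np.mean(per_sample), rel=1e-4)

    def test_false_positive_monotonicity(self):
        truth = np.zeros((3, 3, 3), np.float32)
        truth[1, 1, 1] = 1
        pred = truth.copy()
        base = asymmetric_loss(pred[None], truth[None])
        pred[0, 0, 0] = 1.0  # add one false positive
        assert asymmetric_loss(pred[None], truth[None]) >= base

    def test_bounded_and_differentiable(self):
        rng = np.random.default_rng(2)
        pred = ad.Tensor(rng.random((1, 4, 4, 4)).astype(np.float32))
        truth = (rng.random((1, 4, 4, 4)) > 0.5).astype(np.float32)
        loss = asymmetric_loss(pred, truth)
        assert 0.0 <= float(loss.data) <= 1.0
        loss.backward()
        assert pred.grad is not None and np.all(np.isfinite(pred.grad))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="grid"):
            asymmetric_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestNormalizeIntensity:
    def test_full_range_maps_to_unit_interval(self):
        rng = np.random.default_rng(3)
        v = ImageVolume(rng.random((8, 8, 8)).astype(np.float32))
        out = normalize_intensity(v)
        assert out.data.min() == pytest.approx(0.0, abs=1e-6)
        assert out.data.max() == pytest.approx(1.0, abs=1e-6)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(4)
        data = rng.random((8, 8, 8)).astype(np.float32)
        a = normalize_intensity(ImageVolume(data))
        b = normalize_intensity(ImageVolume(3.5 * data + 120.0))
        np.testing.assert_allclose(a.data, b.data, atol=1e-5)

    def test_constant_volume(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_intensity(ImageVolume(np.full((4, 4, 4), 7.0)))
        assert np.all(out.data == 0.5)


class TestAugmentation:
    def _triple(self, seed=5):
        rng = np.random.default_rng(seed)
        img = rng.random((16, 16, 16)).astype(np.float32)
        mask = np.zeros((16, 16, 16), np.uint8)
        mask[5:10, 6:11, 7:12] = 1
        sppm = rng.random((16, 16, 16)).astype(np.float32)
        return img, mask, sppm

    def test_zero_ranges_identity(self):
        img, mask, sppm = self._triple()
        out = augment_rotation(img, mask, sppm, np.random.default_rng(0),
                               ranges=(0, 0, 0))
        np.testing.assert_array_equal(out[0], img)
        np.testing.assert_array_equal(out[1], mask)

    def test_fixed_seed_reproducible(self):
        img, mask, sppm = self._triple()
        a = augment_rotation(img, mask, sppm, np.random.default_rng(9))
        b = augment_rotation(img, mask, sppm, np.random.default_rng(9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_quarter_turn_conserves_mask_volume(self):
        from nigraseg.training import _rotate
        _, mask, _ = self._triple()
        rotated = _rotate(mask.astype(np.float32), np.array([0, 0, 90.0]),
                          order=0)
        assert rotated.sum() == mask.sum()  # pure index permutation


class TestFolds:
    def test_partition_properties(self):
        folds = make_folds(list(range(10)), k=5, seed=0)
        assert len(folds) == 5
        assert all(len(f) == 2 for f in folds)
        assert sorted(sum(folds, [])) == list(range(10))

    def test_seed_determinism(self):
        assert make_folds(list(range(17)), 4, seed=3) == \
            make_folds(list(range(17)), 4, seed=3)

    def test_near_equal_sizes_271_cases(self):
        folds = make_folds(list(range(271)), k=10, seed=1)
        assert sorted(len(f) for f in folds) == [27] * 9 + [28]

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            make_folds([1, 2], k=3, seed=0)


def _toy_cases(n, rng, edge=16):
    cases = []
    for _ in range(n):
        mask = np.zeros((edge,) * 3, np.float32)
        c = rng.integers(5, edge - 5, size=3)
        mask[c[0] - 2:c[0] + 2, c[1] - 2:c[1] + 2, c[2] - 2:c[2] + 2] = 1
        img = 0.3 + 0.5 * mask + rng.normal(0, 0.05, mask.shape)
        cases.append((img.astype(np.float32), mask.copy(),
                      mask.astype(np.uint8)))
    return cases


class TestTrainLoop:
    def test_zero_epochs_returns_initial_weights(self):
        net = build_unet3d(NetConfig(depth=2, base_channels=4, in_shape=16,
                                     attention="none", init_seed=0))
        w0 = {k: v.copy() for k, v in net.state_dict().items()}
        model, hist = train(net, [], [], TrainConfig(epochs=0))
        assert hist.train_loss == [] and hist.best_epoch == -1
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, w0[k])

    def test_loss_decreases_and_history_consistent(self):
        rng = np.random.default_rng(6)
        cases = _toy_cases(4, rng)
        net = build_unet3d(NetConfig(depth=2, base_channels=4, in_shape=16,
                                     attention="priority", dropout_rate=0.1,
                                     init_seed=0))
        cfg = TrainConfig(epochs=6, seed=0, lr=0.01,
                          rotation_deg=(0, 0, 0))
        model, hist = train(net, cases[:3], cases[3:], cfg)
        assert len(hist.train_loss) == len(hist.val_dice) == 6
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert 0 <= hist.best_epoch < 6

    def test_full_determinism_under_fixed_seed(self):
        rng = np.random.default_rng(7)
        cases = _toy_cases(3, rng)
        cfg = TrainConfig(epochs=3, seed=11, lr=0.01)
        hists = []
        for _ in range(2):
            net = build_unet3d(NetConfig(depth=2, base_channels=4,
                                         in_shape=16, attention="priority",
                                         dropout_rate=0.1, init_seed=4))
            _, hist = train(net, cases[:2], cases[2:], cfg)
            hists.append(hist)
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].val_dice == hists[1].val_dice

    def test_single_case_memorization(self):
        # duplicated single case as train and val: validation Dice must
        # approach 1 (overfit smoke test)
        rng = np.random.default_rng(8)
        cases = _toy_cases(1, rng)
        net = build_unet3d(NetConfig(depth=2, base_channels=8, in_shape=16,
                                     attention="priority", dropout_rate=0.0,
                                     init_seed=1))
        cfg = TrainConfig(epochs=30, seed=0, lr=0.01,
                          rotation_deg=(0, 0, 0))
        _, hist = train(net, cases, cases, cfg)
        assert max(hist.val_dice) > 0.95


class TestAdam:
    def test_single_step_descends_quadratic(self):
        p = ad.Tensor(np.array([3.0], np.float32), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            loss = ad.mul(p, p)
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert abs(float(p.data[0])) < 0.05
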