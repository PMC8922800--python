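"""Loss laws, stage training behaviour, and assembly contracts."""

import dataclasses

import numpy as np
import pytest

from hipseg import engine as eg
from hipseg import models, training
from hipseg.training import LossWeights, TrainConfig


class TestDiceLoss:
    def test_perfect_prediction_is_zero(self):
        t = (np.random.default_rng(0).random((8, 8)) > 0.5).astype(float)
        assert training.dice_loss(t, t) == pytest.approx(0.0, abs=1e-5)

    def test_total_miss_is_one(self):
        t = np.zeros((8, 8))
        t[:4] = 1.0
        assert training.dice_loss(1.0 - t, t) == pytest.approx(1.0, abs=1e-5)

    def test_uniform_half_prediction_closed_form(self):
        # pred = 0.5 everywhere, k ones among n pixels:
        # dice = 1 - (2*0.5*k)/(0.5n + k), here n=100, k=20 -> 1 - 20/70
        n, k = 100, 20
        t = np.zeros(n)
        t[:k] = 1.0
        expected = 1.0 - (2 * 0.5 * k) / (0.5 * n + k)
        assert training.dice_loss(np.full(n, 0.5), t) == pytest.approx(expected, abs=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            training.dice_loss(np.zeros((4, 4)), np.zeros((4, 5)))


class TestCombinedLoss:
    def test_reduces_to_dice_when_b_zero(self):
        rng = np.random.default_rng(1)
        p, t = rng.random((6, 6)), (rng.random((6, 6)) > 0.5).astype(float)
        w = LossWeights(a=1.0, b=0.0)
        assert training.combined_loss(p, t, w) == pytest.approx(training.dice_loss(p, t))

    def test_reduces_to_cross_entropy_when_a_zero(self):
        rng = np.random.default_rng(2)
        p, t = rng.uniform(0.1, 0.9, (6, 6)), (rng.random((6, 6)) > 0.5).astype(float)
        w = LossWeights(a=0.0, b=1.0)
        assert training.combined_loss(p, t, w) == pytest.approx(
            training.cross_entropy_loss(p, t)
        )

    def test_linear_in_weights(self):
        rng = np.random.default_rng(3)
        p, t = rng.uniform(0.1, 0.9, (6, 6)), (rng.random((6, 6)) > 0.5).astype(float)
        one = training.combined_loss(p, t, LossWeights(a=1.0, b=1.0))
        two = training.combined_loss(p, t, LossWeights(a=2.0, b=2.0))
        assert two == pytest.approx(2.0 * one)

    def test_both_weights_zero_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(a=0.0, b=0.0)

    def test_tensor_and_array_losses_agree(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.1, 0.9, (2, 1, 6, 6))
        t = (rng.random((2, 1, 6, 6)) > 0.5).astype(np.float64)
        w = LossWeights()
        tensor_val = float(training._combined_loss_t(eg.Tensor(p), t, w).data)
        assert tensor_val == pytest.approx(training.combined_loss(p, t, w), rel=1e-6)


class TestSupervisedLoss:
    def _data(self):
        rng = np.random.default_rng(5)
        heads = [rng.uniform(0.1, 0.9, (6, 6)) for _ in range(2)]
        t = (rng.random((6, 6)) > 0.5).astype(float)
        return heads, t

    def test_single_head_weight_one_equals_combined(self):
        heads, t = self._data()
        w = LossWeights(head_weights=(1.0,))
        assert training.supervised_loss(heads[:1], t, w) == pytest.approx(
            training.combined_loss(heads[0], t, w)
        )

    def test_perfect_heads_give_zero(self):
        t = np.zeros((6, 6))
        t[2:4] = 1.0
        w = LossWeights(head_weights=(0.5, 1.0))
        assert training.supervised_loss([t, t], t, w) == pytest.approx(0.0, abs=1e-4)

    def test_zero_weight_ignores_first_head(self):
        heads, t = self._data()
        w = LossWeights(head_weights=(0.0, 1.0))
        assert training.supervised_loss(heads, t, w) == pytest.approx(
            training.combined_loss(heads[1], t, w)
        )

    def test_head_count_mismatch_rejected(self):
        heads, t = self._data()
        with pytest.raises(ValueError):
            training.supervised_loss(heads, t, LossWeights(head_weights=(1.0,)))


def _synthetic_halves(n, rows, cols, seed=0, with_femur=True):
    """Tiny synthetic half-slices: a bright disk (femur) and a rim (pelvis)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        femur = np.zeros((rows, cols), np.float32)
        bone = np.zeros((rows, cols), np.float32)
        positive = with_femur and (i % 2 == 0)
        if positive:
            r0, c0 = rng.integers(4, rows - 4), rng.integers(4, cols - 4)
            rr, cc = np.ogrid[:rows, :cols]
            femur[(rr - r0) ** 2 + (cc - c0) ** 2 <= 9] = 1.0
        bone[:3, :] = 1.0
        bone = np.maximum(bone, femur)
        img = np.clip(bone + 0.05 * rng.standard_normal((rows, cols)), 0, 1).astype(
            np.float32
        )
        out.append(
            training.HalfSample(
                bone_image=img,
                femur_image=img,
                bone_mask=bone,
                femur_mask=femur,
                has_femur=bool(femur.any()),
            )
        )
    return out


TINY = models.NetworkConfig(in_rows=16, in_cols=16, base_channels=4, seed=0)
TINY_CLS = models.NetworkConfig(in_rows=32, in_cols=16, base_channels=4, seed=0)


class TestTrainStage:
    def test_upward_loss_decreases_on_small_dataset(self):
        samples = _synthetic_halves(20, 16, 16)
        cfg = TrainConfig(epochs=12, batch_size=8, seed=0)
        _, history = training.train_stage("upward", samples, cfg, TINY)
        assert history[-1] < history[0]

    def test_classifier_fits_its_training_set(self):
        samples = _synthetic_halves(24, 32, 16, seed=1)
        cfg = TrainConfig(epochs=25, batch_size=8, seed=0)
        handle, _ = training.train_stage("classifier", samples, cfg, TINY_CLS)
        x = np.stack([s.bone_image for s in samples])[:, None]
        pred = handle(eg.Tensor(x)).data.ravel() > 0.5
        truth = np.array([s.has_femur for s in samples])
        assert (pred == truth).mean() > 0.9

    def test_main_stage_uses_only_femur_positive_slices(self):
        samples = _synthetic_halves(10, 16, 16, with_femur=False)
        cfg = TrainConfig(epochs=1, batch_size=4, seed=0)
        with pytest.raises(ValueError, match="femur"):
            training.train_stage("main", samples, cfg, TINY)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            training.train_stage("upward", [], TrainConfig(), TINY)

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            training.train_stage("sideways", _synthetic_halves(4, 16, 16), TrainConfig(), TINY)

    def test_fixed_seed_reproduces_loss_trajectory(self):
        samples = _synthetic_halves(12, 16, 16)
        cfg = TrainConfig(epochs=3, batch_size=4, seed=9)
        _, h1 = training.train_stage("upward", samples, cfg, TINY)
        _, h2 = training.train_stage("upward", samples, cfg, TINY)
        assert h1 == h2

    def test_gradient_flows_to_every_head_of_main_net(self):
        net = models.build_main_hourglass(TINY)
        rng = np.random.default_rng(0)
        x = eg.Tensor(rng.random((2, 1, 16, 16), np.float32))
        fusion = eg.Tensor(rng.random((2, 1, 16, 16), np.float32))
        target = (rng.random((2, 1, 16, 16)) > 0.7).astype(np.float32)
        heads = net(x, fusion)
        w = LossWeights(head_weights=(0.5, 1.0))
        loss = None
        for hw, h in zip(w.head_weights, heads):
            term = hw * training._combined_loss_t(h, target, w)
            loss = term if loss is None else loss + term
        loss.backward()
        for st in net.module.stages:
            g = st["head"].weight.grad
            assert g is not None and np.isfinite(g).all() and np.abs(g).sum() > 0


class TestAssemble:
    def _handles(self, cfg_seg=TINY_CLS):
        up = models.build_upward_unet(cfg_seg)
        mn = models.build_main_hourglass(cfg_seg)
        cl = models.build_layer_classifier(cfg_seg)
        return up, mn, cl

    def test_assembling_fresh_nets_is_callable(self):
        pipe = training.assemble(*self._handles())
        res = pipe.upward(eg.Tensor(np.zeros((1, 1, 32, 16), np.float32)))
        assert res[0].data.shape == (1, 1, 32, 16)

    def test_mismatched_input_sizes_rejected(self):
        up, mn, cl = self._handles()
        other = dataclasses.replace(TINY_CLS, in_rows=64, in_cols=32)
        with pytest.raises(ValueError, match="spatial"):
            training.assemble(models.build_upward_unet(other), mn, cl)

    def test_wrong_role_order_rejected(self):
        up, mn, cl = self._handles()
        with pytest.raises(ValueError, match="role"):
            training.assemble(mn, up, cl)
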