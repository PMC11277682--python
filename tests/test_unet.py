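"""Architecture, losses, gradients, and the training loop contract."""

import numpy as np
import pytest

from autoctr import unet as un


class TestArchitecture:
    def test_reference_configuration_parameter_count(self):
        # five levels, base 16, two convs per block, 2-channel head
        assert un.count_parameters(un.UNetConfig()) == 1_940_834
        assert round(un.count_parameters() / 1e6, 2) == 1.94

    def test_default_model_shape_contract(self):
        model = un.build_unet(rng=np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(1, 1, 256, 256))
        out = model.forward(x.astype(np.float32))
        assert out.shape == (1, 2, 256, 256)
        assert (out > 0).all() and (out < 1).all()

    def test_tiny_model_shape_contract(self):
        cfg = un.UNetConfig(input_shape=(32, 32, 1), n_levels=2, base_filters=4)
        model = un.build_unet(cfg, np.random.default_rng(0))
        out = model.forward(np.zeros((3, 1, 32, 32), np.float32))
        assert out.shape == (3, 2, 32, 32)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            un.UNetConfig(input_shape=(100, 100, 1), n_levels=5)

    def test_doubling_base_filters_roughly_quadruples_parameters(self):
        small = un.count_parameters(un.UNetConfig(base_filters=16))
        big = un.count_parameters(un.UNetConfig(base_filters=32))
        assert 3.5 < big / small < 4.5

    def test_second_output_channel_costs_seventeen_parameters(self):
        two = un.count_parameters(un.UNetConfig(out_channels=2))
        one = un.count_parameters(un.UNetConfig(out_channels=1))
        assert two - one == 17  # 16 weights + 1 bias of the 1x1 head

    def test_overlapping_probabilities_expressible(self):
        # per-channel sigmoid: both heart and lung probability can exceed
        # 0.5 at the same pixel (softmax could not express this)
        model = un.build_unet(un.UNetConfig(input_shape=(16, 16, 1),
                                            n_levels=2, base_filters=4),
                              np.random.default_rng(0))
        model.out_conv.b[:] = 3.0  # push both channels high
        out = model.forward(np.zeros((1, 1, 16, 16), np.float32))
        assert ((out[0, 0] > 0.5) & (out[0, 1] > 0.5)).any()


class TestLosses:
    def test_dice_zero_at_perfect_binary_prediction(self):
        t = (np.random.default_rng(0).random((2, 8, 8)) > 0.5).astype(float)
        assert un.dice_loss(t, t, smooth=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_dice_plug_in_values(self):
        n = 16
        assert un.dice_loss(np.ones((4, 4)), np.zeros((4, 4)), smooth=1.0) \
            == pytest.approx(1 - 1 / (n + 1))
        assert un.dice_loss(np.full((4, 4), 0.5), np.ones((4, 4)), smooth=0.0) \
            == pytest.approx(1 / 3)

    def test_focal_plug_in_value(self):
        # positive pixel at p=0.5, gamma=2, alpha=0.25
        got = un.focal_loss(np.full((1, 1), 0.5), np.ones((1, 1)),
                            alpha=0.25, gamma=2.0)
        assert got == pytest.approx(0.25 * 0.25 * np.log(2))

    def test_focal_gamma_zero_is_half_bce(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, (16, 16))
        t = (rng.random((16, 16)) > 0.5).astype(float)
        bce = -np.mean(t * np.log(p) + (1 - t) * np.log(1 - p))
        got = un.focal_loss(p, t, alpha=0.5, gamma=0.0)
        assert got == pytest.approx(0.5 * bce, abs=1e-6)

    def test_focal_near_zero_at_perfect_prediction(self):
        t = (np.random.default_rng(2).random((8, 8)) > 0.5).astype(float)
        assert un.focal_loss(t, t) < 1e-10

    @pytest.mark.parametrize("weights,expect", [
        ((1.0, 0.0), "focal"),
        ((0.0, 1.0), "dice"),
    ])
    def test_combined_loss_degenerate_weights(self, weights, expect):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, (8, 8))
        t = (rng.random((8, 8)) > 0.5).astype(float)
        cfg = un.LossConfig(focal_weight=weights[0], dice_weight=weights[1])
        got = un.combined_loss(p, t, cfg)
        ref = (un.focal_loss(p, t, cfg.focal_alpha, cfg.focal_gamma)
               if expect == "focal" else un.dice_loss(p, t, cfg.dice_smooth))
        assert got == pytest.approx(ref)

    def test_losses_decrease_toward_truth(self):
        # moving one pixel's probability toward its label lowers both losses
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, (8, 8))
        t = (rng.random((8, 8)) > 0.5).astype(float)
        p_better = p + 0.1 * (t - p)
        assert un.focal_loss(p_better, t) < un.focal_loss(p, t)
        assert un.dice_loss(p_better, t) < un.dice_loss(p, t)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            un.dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))
        with pytest.raises(ValueError):
            un.focal_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = un.UNetConfig(input_shape=(8, 8, 1), n_levels=2, base_filters=2)
        rng = np.random.default_rng(0)
        model = un.build_unet(cfg, rng)
        x = rng.normal(size=(2, 1, 8, 8)).astype(np.float32)
        t = (rng.random((2, 2, 8, 8)) > 0.5).astype(np.float32)
        lcfg = un.LossConfig()

        prob = model.forward(x)
        _, dprob = un._combined_loss_grad(prob, t, lcfg)
        model.backward(dprob)
        layers = list(model.layers())
        eps = 1e-3
        for li in (0, 1, 2, 4, len(layers) - 1):
            layer = layers[li]
            idx = tuple(rng.integers(0, s) for s in layer.W.shape)
            analytic = float(layer.dW[idx])
            old = layer.W[idx]
            layer.W[idx] = old + eps
            lp, _ = un._combined_loss_grad(model.forward(x), t, lcfg)
            layer.W[idx] = old - eps
            lm, _ = un._combined_loss_grad(model.forward(x), t, lcfg)
            layer.W[idx] = old
            numeric = (lp - lm) / (2 * eps)
            assert analytic == pytest.approx(numeric, rel=5e-2, abs=1e-5)


@pytest.fixture(scope="module")
def tiny_sets():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(4, 16, 16)).astype(np.float32)
    y = (rng.random((4, 2, 16, 16)) > 0.5).astype(np.float32)
    return (x, y), (x[:2], y[:2])


class TestTrainingLoop:
    def _model(self):
        cfg = un.UNetConfig(input_shape=(16, 16, 1), n_levels=2, base_filters=2)
        return un.build_unet(cfg, np.random.default_rng(1))

    def test_one_epoch_smoke(self, tiny_sets):
        train_set, val_set = tiny_sets
        hist = un.train(self._model(), train_set, val_set,
                        un.TrainingConfig(epochs=1, batch_size=2, seed=0))
        assert len(hist) == 1
        assert np.isfinite(hist.train_loss[0]) and np.isfinite(hist.val_loss[0])

    def test_lr_trace_non_increasing_and_floored(self, tiny_sets):
        train_set, val_set = tiny_sets
        tcfg = un.TrainingConfig(epochs=12, batch_size=4, seed=0,
                                 plateau_patience=1, plateau_factor=0.1,
                                 min_lr=1e-5)
        hist = un.train(self._model(), train_set, val_set, tcfg)
        lrs = np.array(hist.lr)
        assert (np.diff(lrs) <= 0).all()
        assert (lrs >= tcfg.min_lr - 1e-12).all()

    def test_fixed_seed_reproduces_history(self, tiny_sets):
        train_set, val_set = tiny_sets
        tcfg = un.TrainingConfig(epochs=2, batch_size=2, seed=5)
        h1 = un.train(self._model(), train_set, val_set, tcfg)
        h2 = un.train(self._model(), train_set, val_set, tcfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_empty_set_rejected(self, tiny_sets):
        _, val_set = tiny_sets
        with pytest.raises(ValueError):
            un.train(self._model(), (np.zeros((0, 16, 16)),
                                     np.zeros((0, 2, 16, 16))), val_set)


class TestPredict:
    def test_range_shape_and_determinism(self):
        cfg = un.UNetConfig(input_shape=(32, 32, 1), n_levels=2, base_filters=4)
        model = un.build_unet(cfg, np.random.default_rng(0))
        img = np.random.default_rng(1).normal(size=(32, 32))
        out1 = un.predict(model, img)
        out2 = un.predict(model, img)
        assert out1.shape == (2, 32, 32)
        assert (out1 >= 0).all() and (out1 <= 1).all()
        np.testing.assert_array_equal(out1, out2)

    def test_shape_mismatch_rejected(self):
        cfg = un.UNetConfig(input_shape=(32, 32, 1), n_levels=2, base_filters=4)
        model = un.build_unet(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            un.predict(model, np.zeros((16, 16)))

    def test_trained_model_segments_held_out_phantom(self, phantom_training_run):
        run = phantom_training_run
        prob = un.predict(run["model"], run["x_val"][0])
        from autoctr.evaluate import iou

        heart_iou = iou(prob[0] > 0.5, run["masks_val"][0][0] > 0.5)
        assert heart_iou >= 0.7


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        cfg = un.UNetConfig(input_shape=(16, 16, 1), n_levels=2, base_filters=2)
        model = un.build_unet(cfg, np.random.default_rng(0))
        img = np.random.default_rng(1).normal(size=(16, 16))
        before = un.predict(model, img)
        path = tmp_path / "ckpt.npz"
        un.save_model(model, path)
        loaded = un.load_model(path)
        np.testing.assert_array_equal(un.predict(loaded, img), before)
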