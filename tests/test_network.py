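import numpy as np
import pytest

from lobeprior import nn
from lobeprior.network import (AttUNet, Hyperparameters, NetConfig,
                               STAGE2_IN_CHANNELS, StagePrediction,
                               stage1_predict, stage2_refine,
                               structure_targets, train_stage)
from lobeprior.volume_io import CTVolume, default_affine


def tiny_cfg(stage=1, **kw):
    in_ch = 1 if stage == 1 else STAGE2_IN_CHANNELS
    return NetConfig(in_channels=in_ch, base_channels=2, depth=2,
                     stage=stage, **kw)


class TestArchitecture:
    def test_stage1_output_shape_and_range(self, rng):
        model = AttUNet(tiny_cfg(1))
        x = rng.random((1, 16, 16, 16)).astype(np.float32)
        act = model.predict(x)
        assert act.shape == (7, 16, 16, 16)
        assert act.min() >= 0.0 and act.max() <= 1.0

    def test_stage2_seven_sigmoid_maps(self, rng):
        model = AttUNet(tiny_cfg(2))
        x = rng.random((13, 16, 16, 16)).astype(np.float32)
        act = model.predict(x)
        assert act.shape == (7, 16, 16, 16)
        assert act.min() >= 0.0 and act.max() <= 1.0

    def test_attention_ablation_switch_runs(self, rng):
        model = AttUNet(tiny_cfg(1, attention=False))
        x = rng.random((1, 16, 16, 16)).astype(np.float32)
        assert model.predict(x).shape == (7, 16, 16, 16)
        assert not any("att" in k for k in model.params)

    def test_incompatible_depth_rejected(self, rng):
        model = AttUNet(tiny_cfg(1))
        with pytest.raises(ValueError, match="depth"):
            model.predict(rng.random((1, 10, 16, 16)).astype(np.float32))

    def test_stage2_channel_invariant(self):
        with pytest.raises(ValueError, match="13"):
            NetConfig(in_channels=12, stage=2)

    def test_stage1_lobe_channels_bounded_by_softmax(self, rng):
        model = AttUNet(tiny_cfg(1))
        act = model.predict(rng.random((1, 16, 16, 16)).astype(np.float32))
        assert np.all(act[:5].sum(axis=0) <= 1.0 + 1e-5)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = AttUNet(tiny_cfg(2))
        x = rng.random((13, 16, 16, 16)).astype(np.float32)
        before = model.predict(x)
        model.save(tmp_path / "m")
        again = AttUNet.load(tmp_path / "m")
        np.testing.assert_array_equal(again.predict(x), before)


class TestStagePredictors:
    def test_stage1_resamples_to_target_size(self, norm_phantom):
        vol, _ = norm_phantom
        model = AttUNet(tiny_cfg(1))
        pred = stage1_predict(model, vol, target_size=(16, 16, 16))
        assert pred.activations.shape == (7, 16, 16, 16)
        assert pred.grid_meta["orig_shape"] == tuple(vol.shape)

    def test_stitching_identity_when_patches_tile_exactly(self, rng):
        model = AttUNet(tiny_cfg(2))
        vol = CTVolume(rng.random((16, 16, 32)), (1, 1, 1),
                       default_affine((1, 1, 1)), normalized=True)
        prior = rng.random((5, 16, 16, 32))
        coarse = StagePrediction(
            rng.random((7, 16, 16, 32)).astype(np.float32), stage=1)
        out = stage2_refine(model, vol, prior, coarse, patch=(16, 16, 16),
                            overlap=0.0)
        # brute-force: two independent forward passes, no averaging
        x_full = np.concatenate([vol.intensities[None], prior,
                                 coarse.activations]).astype(np.float32)
        left = model.predict(x_full[:, :, :, :16])
        right = model.predict(x_full[:, :, :, 16:])
        np.testing.assert_allclose(out.activations[:, :, :, :16], left,
                                   atol=1e-6)
        np.testing.assert_allclose(out.activations[:, :, :, 16:], right,
                                   atol=1e-6)

    def test_overlap_stitching_matches_per_voxel_mean(self, rng):
        model = AttUNet(tiny_cfg(2))
        shape = (16, 16, 24)
        vol = CTVolume(rng.random(shape), (1, 1, 1),
                       default_affine((1, 1, 1)), normalized=True)
        prior = rng.random((5,) + shape)
        coarse = StagePrediction(
            rng.random((7,) + shape).astype(np.float32), stage=1)
        out = stage2_refine(model, vol, prior, coarse, patch=(16, 16, 16),
                            overlap=0.5)
        x_full = np.concatenate([vol.intensities[None], prior,
                                 coarse.activations]).astype(np.float32)
        acc = np.zeros((7,) + shape)
        cnt = np.zeros(shape)
        for w0 in (0, 8):
            pred = model.predict(x_full[:, :, :, w0:w0 + 16])
            acc[:, :, :, w0:w0 + 16] += pred
            cnt[:, :, w0:w0 + 16] += 1
        np.testing.assert_allclose(out.activations, acc / cnt, atol=1e-6)

    def test_oversized_patch_shrunk_with_warning(self, rng, caplog):
        model = AttUNet(tiny_cfg(2))
        shape = (16, 16, 16)
        vol = CTVolume(rng.random(shape), (1, 1, 1),
                       default_affine((1, 1, 1)), normalized=True)
        prior = rng.random((5,) + shape)
        coarse = StagePrediction(
            rng.random((7,) + shape).astype(np.float32), stage=1)
        with caplog.at_level("WARNING"):
            out = stage2_refine(model, vol, prior, coarse, patch=(32, 32, 32))
        assert out.activations.shape == (7,) + shape
        assert any("shrunk" in r.message for r in caplog.records)

    def test_same_input_twice_identical(self, rng):
        model = AttUNet(tiny_cfg(1))
        x = rng.random((1, 16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(model.predict(x), model.predict(x))


class TestTraining:
    def _samples(self, rng, n=2):
        out = []
        for _ in range(n):
            x = rng.random((1, 16, 16, 16)).astype(np.float32)
            y = np.zeros((16, 16, 16), dtype=np.int16)
            y[4:12, 4:12, 4:12] = rng.integers(1, 6)
            out.append((x, y))
        return out

    def test_overfit_run_decreases_loss(self, rng):
        model = AttUNet(tiny_cfg(1))
        s = self._samples(rng, 2)
        _, hist = train_stage(model, s, s, Hyperparameters(lr=5e-3, epochs=4,
                                                           seed=0))
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_lr_schedule_follows_exponential_decay(self, rng):
        model = AttUNet(tiny_cfg(1))
        s = self._samples(rng, 1)
        hp = Hyperparameters(lr=1e-4, lr_decay=0.985, epochs=3, seed=0)
        _, hist = train_stage(model, s, s, hp)
        for k, lr in enumerate(hist["lr"]):
            assert lr == pytest.approx(1e-4 * 0.985**k)

    def test_best_checkpoint_is_min_val_loss(self, rng):
        model = AttUNet(tiny_cfg(1))
        s = self._samples(rng, 2)
        model, hist = train_stage(model, s[:1], s[1:],
                                  Hyperparameters(lr=5e-3, epochs=5, seed=0))
        # loss of the returned model equals the minimum recorded val loss
        x, y = s[1]
        final = float(model.loss(x, y).data)
        assert final == pytest.approx(min(hist["val_loss"]), abs=1e-5)

    def test_empty_data_rejected(self, rng):
        model = AttUNet(tiny_cfg(1))
        with pytest.raises(ValueError):
            train_stage(model, [], self._samples(rng, 1), Hyperparameters())

    def test_training_deterministic_across_runs(self, rng):
        s = self._samples(rng, 2)
        hists = []
        for _ in range(2):
            model = AttUNet(tiny_cfg(1))
            _, h = train_stage(model, s, s,
                               Hyperparameters(lr=5e-3, epochs=3, seed=7))
            hists.append(h)
        assert hists[0]["train_loss"] == hists[1]["train_loss"]
        assert hists[0]["val_loss"] == hists[1]["val_loss"]


class TestTargets:
    def test_structure_targets_layout(self, phantom48_clean):
        _, lab, _ = phantom48_clean
        t = structure_targets(lab.labels)
        assert t.shape == (7,) + lab.shape
        np.testing.assert_array_equal(t[5], ((lab.labels >= 1)
                                             & (lab.labels <= 5)))
        np.testing.assert_array_equal(t[6], lab.labels == 6)
        np.testing.assert_array_equal(t[2], lab.labels == 3)
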