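"""Full network assembly, focal loss and checkpointing."""

import numpy as np
import pytest

from trilightnet import ModelConfig, TriLightNet, count_params_flops, focal_loss
from trilightnet.autodiff import Tensor, no_grad
from trilightnet.image_encoder import EncoderConfig, ResNet3d
from trilightnet.mmca import tokens_from_featuremap
from trilightnet.network import (
    FocalLossConfig,
    Prediction,
    load_checkpoint,
    save_checkpoint,
)
from trilightnet.nn import Linear

rng = np.random.default_rng(123)


def _batch(b=2, shape=(24, 32, 24)):
    return (
        Tensor(rng.standard_normal((b, 1) + shape).astype(np.float32)),
        Tensor(rng.standard_normal((b, 1) + shape).astype(np.float32)),
        Tensor(rng.standard_normal((b, 7)).astype(np.float32)),
    )


class TestEncoderShapes:
    def test_full_preset_stride_arithmetic(self):
        cfg = EncoderConfig.from_preset("full")
        assert cfg.output_spatial((96, 128, 96)) == (3, 4, 3)
        assert cfg.out_channels == 256

    def test_test_preset_forward_shape(self):
        cfg = EncoderConfig.from_preset("test")
        assert cfg.output_spatial((24, 32, 24)) == (3, 4, 3)
        enc = ResNet3d(cfg, np.random.default_rng(0))
        enc.eval()
        with no_grad():
            out = enc(Tensor(rng.standard_normal((2, 1, 24, 32, 24)).astype(np.float32)))
        assert out.shape == (2, 64, 3, 4, 3)

    def test_identical_volumes_identical_features(self):
        enc = ResNet3d(EncoderConfig.from_preset("test"), np.random.default_rng(0))
        enc.eval()
        vol = rng.standard_normal((1, 1, 24, 32, 24)).astype(np.float32)
        with no_grad():
            out = enc(Tensor(np.concatenate([vol, vol])))
        assert np.array_equal(out.data[0], out.data[1])

    def test_too_small_input_rejected(self):
        cfg = EncoderConfig.from_preset("full")
        with pytest.raises(ValueError):
            cfg.output_spatial((16, 16, 16))

    def test_nonincreasing_widths_rejected(self):
        with pytest.raises(ValueError):
            EncoderConfig(stage_widths=(32, 32, 64, 128))


class TestForward:
    def test_smoke_batch_two_finite_logits(self):
        model = TriLightNet(ModelConfig(), seed=0)
        model.eval()
        with no_grad():
            logits = model(*_batch(2))
        assert logits.shape == (2,)
        assert np.all(np.isfinite(logits.data))

    def test_identical_subjects_identical_predictions(self):
        model = TriLightNet(ModelConfig(), seed=0)
        mri, pet, cli = _batch(1)
        doubled = (
            Tensor(np.concatenate([mri.data, mri.data])),
            Tensor(np.concatenate([pet.data, pet.data])),
            Tensor(np.concatenate([cli.data, cli.data])),
        )
        preds = model.predict(*doubled)
        assert preds[0].logit == preds[1].logit

    def test_forward_equals_manual_chaining(self):
        from trilightnet.autodiff import gelu

        model = TriLightNet(ModelConfig(), seed=1)
        model.eval()
        mri, pet, cli = _batch(2)
        with no_grad():
            logits = model(mri, pet, cli).data
            f_cli = model.tabular(cli)
            f_mri = model.hbam_mri(model.mri_encoder(mri), f_cli)
            f_pet = model.hbam_pet(model.pet_encoder(pet), f_cli)
            fused = model.mmca(tokens_from_featuremap(f_mri), tokens_from_featuremap(f_pet))
            pooled = fused.mean(axis=1)
            manual = model.head_fc2(gelu(model.head_fc1(model.head_norm(pooled)))).data
        assert np.array_equal(logits, manual.reshape(-1))

    def test_prediction_invariant(self):
        p = Prediction.from_logit(0.0)
        assert p.probability == 0.5 and p.label == 1
        assert Prediction.from_logit(-3.0).label == 0


class TestFocalLoss:
    def test_reduces_to_cross_entropy(self):
        """At gamma=0, alpha=1 the modulating factor and the class weight
        both vanish and the loss is plain cross-entropy to 1e-12 (both
        classes via the literal single-factor form; positives also in
        the alpha-balanced default form, where alpha_t = 1)."""
        r = np.random.default_rng(0)
        p = r.uniform(1e-6, 1 - 1e-6, 1000)
        y = r.integers(0, 2, 1000)
        ce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
        got = focal_loss(
            p, y, FocalLossConfig(alpha=1.0, gamma=0.0, literal_form=True), reduction="none"
        )
        assert np.abs(got - ce).max() < 1e-12
        pos = y == 1
        got_default = focal_loss(
            p[pos], y[pos], FocalLossConfig(alpha=1.0, gamma=0.0), reduction="none"
        )
        assert np.abs(got_default - ce[pos]).max() < 1e-12

    def test_cross_entropy_at_half(self):
        assert abs(focal_loss(0.5, 1, FocalLossConfig(alpha=1.0, gamma=0.0)) - 0.6931) < 1e-4

    def test_hand_worked_value(self):
        """y=1, p=0.9, alpha=0.25, gamma=2 -> 0.25 * 0.01 * 0.105361."""
        got = focal_loss(0.9, 1, FocalLossConfig(alpha=0.25, gamma=2.0))
        assert abs(got - 2.634e-4) < 1e-6

    def test_easy_negative_vanishes(self):
        assert focal_loss(1e-7, 0, FocalLossConfig()) < 1e-6

    def test_never_exceeds_cross_entropy(self):
        r = np.random.default_rng(1)
        p = r.uniform(1e-6, 1 - 1e-6, 1000)
        y = r.integers(0, 2, 1000)
        fl = focal_loss(p, y, FocalLossConfig(alpha=0.75, gamma=2.0), reduction="none")
        ce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert np.all(fl <= ce + 1e-12)

    def test_literal_form_as_printed(self):
        """Single (1-p)^gamma factor multiplying the full cross-entropy."""
        p, y, a, g = 0.8, 0, 0.6, 2.0
        got = focal_loss(p, y, FocalLossConfig(alpha=a, gamma=g, literal_form=True))
        expected = -a * (1 - p) ** g * np.log(1 - p)
        assert abs(got - expected) < 1e-12

    def test_gradient_matches_finite_differences(self):
        r = np.random.default_rng(2)
        p = r.uniform(0.05, 0.95, 20)
        y = r.integers(0, 2, 20)
        t = Tensor(p, requires_grad=True)
        focal_loss(t, y, FocalLossConfig(), reduction="mean").backward()
        eps = 1e-7
        for i in range(20):
            pp, pm = p.copy(), p.copy()
            pp[i] += eps
            pm[i] -= eps
            fd = (
                focal_loss(pp, y, FocalLossConfig()) - focal_loss(pm, y, FocalLossConfig())
            ) / (2 * eps)
            assert abs(t.grad[i] - fd) < 1e-4

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(0.5, 2, FocalLossConfig())


class TestCheckpoint:
    def test_save_load_bit_exact_logits(self, tmp_path):
        model = TriLightNet(ModelConfig(), seed=3)
        mri, pet, cli = _batch(2)
        before = model.predict(mri, pet, cli)
        path = tmp_path / "model.ckpt.npz"
        save_checkpoint(model, path, extra={"note": "test"})
        loaded, extra = load_checkpoint(path)
        after = loaded.predict(mri, pet, cli)
        assert extra == {"note": "test"}
        assert all(a.logit == b.logit for a, b in zip(before, after))

    def test_missing_entry_rejected(self, tmp_path):
        model = TriLightNet(ModelConfig(), seed=3)
        state = model.state_dict()
        state.pop(next(iter(state)))
        with pytest.raises(KeyError):
            model.load_state_dict(state)


class TestParamsFlops:
    def test_linear_param_count(self):
        lin = Linear(7, 64)
        assert sum(int(np.prod(p.shape)) for _, p in lin.named_parameters()) == 7 * 64 + 64

    def test_model_params_equal_sum_of_named_arrays(self):
        cfg = ModelConfig()
        model = TriLightNet(cfg, seed=0)
        n, flops = count_params_flops(cfg)
        assert n == sum(int(np.prod(p.shape)) for _, p in model.named_parameters())
        assert flops > 0

    def test_width_doubling_roughly_quadruples_conv_params(self):
        base = EncoderConfig(stage_widths=(8, 16, 32, 64), blocks_per_stage=(1, 1, 1, 1))
        double = EncoderConfig(stage_widths=(16, 32, 64, 128), blocks_per_stage=(1, 1, 1, 1))

        def conv_params(cfg):
            enc = ResNet3d(cfg, np.random.default_rng(0))
            return sum(
                int(np.prod(p.shape))
                for name, p in enc.named_parameters()
                if "conv" in name or "stem" in name
            )

        ratio = conv_params(double) / conv_params(base)
        assert 3.5 < ratio < 4.5
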