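"""Architecture contracts: strip pooling, ASPP, encoder/decoder, inference."""

from __future__ import annotations

import numpy as np
import pytest

from ridgeseg import nn
from ridgeseg.model import (ASPP, ASPNet, ModelConfig, StripPool,
                            load_checkpoint, receptive_field_offsets)
from ridgeseg.nn import functional as F
from ridgeseg.nn.tensor import Tensor


def strip_pool_loop_oracle(x: np.ndarray, sp: StripPool) -> np.ndarray:
    """Explicit per-pixel walk-through of the strip-pooling contract."""
    n, c, h, w = x.shape
    wh = sp.conv_h.weight.data  # (C, C, 3, 1)
    ww = sp.conv_w.weight.data  # (C, C, 1, 3)
    bh = sp.conv_h.bias.data
    bw = sp.conv_w.bias.data
    wf = sp.conv_fuse.weight.data  # (C, C, 1, 1)
    bf = sp.conv_fuse.bias.data
    out = np.zeros_like(x)
    for bi in range(n):
        row_mean = x[bi].mean(axis=2)  # (C, H): column-average of each row
        col_mean = x[bi].mean(axis=1)  # (C, W)
        # length-3 convolution along the pooled axis, zero padded
        rp = np.zeros_like(row_mean)
        cp = np.zeros_like(col_mean)
        for co in range(c):
            for i in range(h):
                acc = bh[co]
                for k in (-1, 0, 1):
                    if 0 <= i + k < h:
                        for ci in range(c):
                            acc += wh[co, ci, k + 1, 0] * row_mean[ci, i + k]
                rp[co, i] = acc
            for j in range(w):
                acc = bw[co]
                for k in (-1, 0, 1):
                    if 0 <= j + k < w:
                        for ci in range(c):
                            acc += ww[co, ci, 0, k + 1] * col_mean[ci, j + k]
                cp[co, j] = acc
        for i in range(h):
            for j in range(w):
                summed = rp[:, i] + cp[:, j]  # pixel-wise sum of expansions
                gate = 1.0 / (1.0 + np.exp(-(wf[:, :, 0, 0] @ summed + bf)))
                out[bi, :, i, j] = x[bi, :, i, j] * gate
    return out


class TestStripPool:
    def test_zero_input_gives_zero_output(self):
        sp = StripPool(3, np.random.default_rng(0))
        out = sp(Tensor(np.zeros((1, 3, 5, 7), dtype=np.float32)))
        assert np.all(out.data == 0)

    @pytest.mark.parametrize("v", [0.0, -0.5, 0.5, 3.0])
    def test_single_pixel_identity_params_closed_form(self, v):
        # with identity convolutions and zero biases a 1x1 input of value v
        # passes both pooled paths unchanged, sums to 2v, and is gated by
        # sigmoid(2v): output v * sigmoid(2v)
        sp = StripPool(1, np.random.default_rng(0))
        sp.conv_h.weight.data[:] = 0
        sp.conv_h.weight.data[0, 0, 1, 0] = 1.0
        sp.conv_w.weight.data[:] = 0
        sp.conv_w.weight.data[0, 0, 0, 1] = 1.0
        sp.conv_fuse.weight.data[:] = 1.0
        out = sp(Tensor(np.full((1, 1, 1, 1), v)))
        expected = v / (1.0 + np.exp(-2.0 * v))
        assert np.allclose(out.data, expected, atol=1e-12)

    @pytest.mark.parametrize("channels", [1, 3, 8])
    def test_matches_per_pixel_loop_oracle(self, channels):
        rng = np.random.default_rng(42 + channels)
        sp = StripPool(channels, np.random.default_rng(7))
        sp.conv_h.bias.data[:] = rng.normal(size=channels)
        sp.conv_w.bias.data[:] = rng.normal(size=channels)
        sp.conv_fuse.bias.data[:] = rng.normal(size=channels)
        x = rng.normal(size=(2, channels, 4, 6)).astype(np.float32)
        assert np.abs(sp(Tensor(x)).data
                      - strip_pool_loop_oracle(x, sp)).max() <= 1e-5

    def test_channel_mismatch_raises(self):
        sp = StripPool(3, np.random.default_rng(0))
        with pytest.raises(ValueError, match="channels"):
            sp(Tensor(np.zeros((1, 4, 5, 5), dtype=np.float32)))


class TestASPP:
    def test_shape_contract(self):
        aspp = ASPP(6, 10, (2, 4, 6), np.random.default_rng(0))
        out = aspp(Tensor(np.random.default_rng(1)
                          .normal(size=(2, 6, 8, 9)).astype(np.float32)))
        assert out.shape == (2, 10, 8, 9)

    def test_zero_input_zero_biases_gives_zero(self):
        aspp = ASPP(3, 4, (2, 4, 6), np.random.default_rng(0))
        out = aspp(Tensor(np.zeros((1, 3, 6, 6), dtype=np.float32)))
        assert np.all(out.data == 0)

    @pytest.mark.parametrize("rate", [1, 2, 6, 12, 18])
    def test_dilated_branch_touches_exact_offsets(self, rate):
        conv = nn.Conv2d(2, 3, 3, np.random.default_rng(rate), padding=rate,
                         dilation=rate)
        offsets = receptive_field_offsets(conv, size=4 * 18 + 1)
        assert offsets == {(dy, dx) for dy in (-rate, 0, rate)
                           for dx in (-rate, 0, rate)}

    def test_oversized_rate_is_zero_padded_not_an_error(self):
        aspp = ASPP(2, 2, (6, 12, 18), np.random.default_rng(0))
        out = aspp(Tensor(np.random.default_rng(1)
                          .normal(size=(1, 2, 4, 4)).astype(np.float32)))
        assert out.shape == (1, 2, 4, 4)
        assert np.isfinite(out.data).all()


class TestForward:
    def test_encoder_shapes_follow_schedule(self, tiny_model):
        x = Tensor(np.random.default_rng(0)
                   .normal(size=(1, 3, 64, 48)).astype(np.float32))
        skips, deepest = tiny_model.encoder_forward(x)
        cs = tiny_model.config.channel_schedule
        assert [s.shape for s in skips] == [
            (1, cs[0], 64, 48), (1, cs[1], 32, 24),
            (1, cs[2], 16, 12), (1, cs[3], 8, 6)]
        assert deepest.shape == (1, cs[4], 4, 3)

    def test_indivisible_input_raises_naming_divisor(self, tiny_model):
        with pytest.raises(ValueError, match="16"):
            tiny_model.encoder_forward(
                Tensor(np.zeros((1, 3, 60, 64), dtype=np.float32)))

    @pytest.mark.parametrize("hw", [(32, 48), (64, 64)])
    def test_full_forward_shape_and_finiteness(self, hw):
        model = ASPNet(ModelConfig(base_channels=4, seed=1))
        h, w = hw
        x = Tensor(np.random.default_rng(0)
                   .normal(size=(2, 3, h, w)).astype(np.float32))
        out = model.forward(x)
        assert out.shape == (2, 2, h, w)
        assert np.isfinite(out.data).all()

    def test_forward_is_deterministic(self, tiny_model):
        x = Tensor(np.random.default_rng(3)
                   .normal(size=(1, 3, 32, 32)).astype(np.float32))
        tiny_model.eval()
        a = tiny_model.forward(x).data
        b = tiny_model.forward(Tensor(x.data.copy())).data
        assert np.array_equal(a, b)

    def test_all_zero_weights_give_all_zero_logits(self):
        model = ASPNet(ModelConfig(base_channels=4, seed=0))
        for p in model.parameters():
            p.data[:] = 0
        out = model.forward(Tensor(np.random.default_rng(0)
                                   .normal(size=(1, 3, 32, 32)).astype(np.float32)))
        assert np.all(out.data == 0)

    def test_every_parameter_receives_gradient(self):
        # no dead branches: cross-entropy on a random batch reaches everything
        model = ASPNet(ModelConfig(base_channels=8, seed=2))
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(2, 3, 32, 32)).astype(np.float32))
        labels = rng.integers(0, 2, (2, 32, 32))
        loss = F.cross_entropy_with_logits(model.forward(x), labels)
        loss.backward()
        dead = [k for k, p in model.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []

    def test_transposed_and_add_variants_run(self):
        cfg = ModelConfig(base_channels=4, seed=0, upsample_mode="transposed",
                          fusion_mode="add")
        out = ASPNet(cfg).forward(Tensor(np.random.default_rng(0)
                                         .normal(size=(1, 3, 32, 32))
                                         .astype(np.float32)))
        assert out.shape == (1, 2, 32, 32)


class TestPredict:
    def test_tied_logits_predict_background(self):
        model = ASPNet(ModelConfig(base_channels=4, seed=0))
        for p in model.parameters():
            p.data[:] = 0  # logits identically zero -> exact tie
        img = np.random.default_rng(0).integers(0, 256, (32, 32, 3), dtype=np.uint8)
        assert np.all(model.predict(img) == 0)

    def test_uniformly_larger_ridge_logit_predicts_all_ridge(self):
        model = ASPNet(ModelConfig(base_channels=4, seed=0))
        for p in model.parameters():
            p.data[:] = 0
        model.head.bias.data[:] = [0.0, 1.0]
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        assert np.all(model.predict(img) == 1)

    def test_predict_consistent_with_logit_argmax(self, tiny_model):
        img = np.random.default_rng(5).integers(0, 256, (32, 32, 3), dtype=np.uint8)
        logits = tiny_model.predict_logits(img)
        assert np.array_equal(tiny_model.predict(img),
                              (logits[1] > logits[0]).astype(np.uint8))


class TestCheckpoint:
    def test_round_trip_preserves_config_and_predictions(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        tiny_model.save_checkpoint(path)
        loaded = load_checkpoint(path)
        assert loaded.config == tiny_model.config
        img = np.random.default_rng(1).integers(0, 256, (32, 32, 3), dtype=np.uint8)
        assert np.array_equal(loaded.predict(img), tiny_model.predict(img))
        assert np.allclose(loaded.predict_logits(img), tiny_model.predict_logits(img))

    def test_config_dict_round_trip(self):
        cfg = ModelConfig(base_channels=8, aspp_rates=(2, 5, 9), seed=3)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(aspp_rates=(12, 6, 18))
        with pytest.raises(ValueError):
            ModelConfig(channel_schedule=(8, 16, 32))
        with pytest.raises(ValueError):
            ModelConfig(upsample_mode="nearest")
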