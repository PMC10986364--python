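import numpy as np
import pytest
from scipy import ndimage

import p3dseize as pz
from p3dseize.model import (ModelConfig, SeizurePredictor, bi_convlstm3d_forward,
                            convlstm3d_step, count_parameters, model_forward,
                            se_attention3d)
from p3dseize.nn import Conv3D, ConvLSTM3DCell, SEAttention3D, sigmoid
import oracles


def tiny_config(**kw):
    base = dict(p3d_channels=(3, 3), p3d_kernels=((1, 3, 3), (3, 1, 1)),
                convlstm_hidden=2, attention_channels=4, attention_reduction=2,
                head_hidden=3, dropout=0.0, seed=1)
    base.update(kw)
    return ModelConfig(**base)


class TestModelConfig:
    def test_reference_validates(self):
        cfg = ModelConfig()
        assert cfg.p3d_channels == (64, 64, 128, 128, 256, 256)
        assert cfg.p3d_kernels[0] == (1, 3, 3) and cfg.p3d_kernels[1] == (3, 1, 1)

    @pytest.mark.parametrize(
        "kw",
        [
            {"attention_channels": 100},  # != 2*hidden
            {"attention_reduction": 7},  # does not divide 512
            {"p3d_channels": (8, 8)},  # misaligned with 6 kernels
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelConfig(**kw)


class TestP3DStack:
    def test_reference_output_shape(self):
        model = SeizurePredictor(ModelConfig())
        x = np.random.default_rng(0).standard_normal((2, 3, 4, 7, 1))
        out = pz.p3d_block_forward(x, model)
        assert out.shape == (2, 3, 4, 7, 256)

    def test_identity_centered_spatial_kernel(self):
        rng = np.random.default_rng(0)
        conv = Conv3D(1, 1, (1, 3, 3), rng)
        w = np.zeros((1, 3, 3, 1, 1))
        w[0, 1, 1, 0, 0] = 1.0
        conv.W.value = w.reshape(-1, 1)
        conv.b.value[:] = 0.0
        x = rng.standard_normal((2, 3, 4, 7, 1))
        out, _ = conv.forward(x)
        assert np.allclose(out, x, atol=1e-12)

    def test_separable_factorization_equals_full_3d_conv(self):
        """Spatial 1x3x3 then feature-axis 3x1x1 (linear, no bias) equals a
        single full 3-D convolution with the outer-product kernel."""
        rng = np.random.default_rng(1)
        ws = rng.standard_normal((3, 3))  # spatial taps (h, w)
        wf = rng.standard_normal(3)  # feature-axis taps
        conv_s = Conv3D(1, 1, (1, 3, 3), rng, bias=False)
        conv_s.W.value = ws.reshape(-1, 1)
        conv_f = Conv3D(1, 1, (3, 1, 1), rng, bias=False)
        conv_f.W.value = wf.reshape(-1, 1)
        x = rng.standard_normal((1, 3, 4, 7, 1))
        mid, _ = conv_s.forward(x)
        out, _ = conv_f.forward(mid)
        # im2col lays patches out in sliding-window order == correlation
        kernel = wf[:, None, None] * ws[None, :, :]
        ref = ndimage.correlate(x[0, :, :, :, 0], kernel, mode="constant")
        assert np.allclose(out[0, :, :, :, 0], ref, atol=1e-6)


class TestConvLSTM3DCell:
    def _cell(self, cin=2, hidden=2, seed=0, **kw):
        return ConvLSTM3DCell(cin, hidden, (1, 1, 1),
                              np.random.default_rng(seed), **kw)

    def test_zero_weights_zero_state(self):
        cell = self._cell()
        for p in cell.params():
            p.value[...] = 0.0
        x = np.random.default_rng(1).standard_normal((2, 3, 4, 7, 2))
        h0, c0 = cell.init_state(2, (3, 4, 7))
        h, c, gates = convlstm3d_step(x, (h0, c0), cell)
        assert np.all(h == 0.0) and np.all(c == 0.0)
        assert np.allclose(gates["o"], 0.5)

    def test_forget_gate_saturation_preserves_cell(self):
        cell = self._cell()
        for p in cell.params():
            p.value[...] = 0.0
        hd = cell.hidden
        cell.conv_x.b.value[hd:2 * hd] = 10.0  # forget bias
        cell.conv_x.b.value[:hd] = -10.0  # input bias
        c0 = np.random.default_rng(2).standard_normal((1, 3, 4, 7, hd))
        h0 = np.zeros_like(c0)
        x = np.random.default_rng(3).standard_normal((1, 3, 4, 7, 2))
        _, c1, _ = convlstm3d_step(x, (h0, c0), cell)
        assert np.allclose(c1, sigmoid(np.array(10.0)) * c0, atol=1e-4)

    def test_gates_lie_in_codomains(self):
        cell = self._cell(seed=5)
        x = 3.0 * np.random.default_rng(6).standard_normal((2, 3, 4, 7, 2))
        h0, c0 = cell.init_state(2, (3, 4, 7))
        _, _, gates = convlstm3d_step(x, (h0, c0), cell)
        for g in ("i", "f", "o"):
            assert np.all((gates[g] > 0) & (gates[g] < 1))
        assert np.all((gates["g"] > -1) & (gates["g"] < 1))

    def test_reduces_to_scalar_lstm(self):
        """On a 1x1x1 grid with one hidden channel the cell is exactly a
        scalar LSTM; agree with an independent oracle to 1e-12."""
        cell = self._cell(cin=1, hidden=1, seed=7)
        rng = np.random.default_rng(8)
        for p in (cell.conv_x.W, cell.conv_h.W, cell.conv_x.b):
            p.value[...] = rng.standard_normal(p.value.shape)
        wx = cell.conv_x.W.value[0]  # (4,) gate order i,f,g,o
        wh = cell.conv_h.W.value[0]
        b = cell.conv_x.b.value
        w = {}
        for k, name in enumerate(("i", "f", "g", "o")):
            w[f"wx_{name}"] = wx[k]
            w[f"wh_{name}"] = wh[k]
            w[f"b_{name}"] = b[k]
        h = np.zeros((1, 1, 1, 1, 1))
        c = np.zeros((1, 1, 1, 1, 1))
        h_ref, c_ref = 0.0, 0.0
        for t in range(10):
            x = rng.standard_normal()
            xt = np.full((1, 1, 1, 1, 1), x)
            h, c, _ = convlstm3d_step(xt, (h, c), cell)
            h_ref, c_ref = oracles.scalar_lstm_step(x, h_ref, c_ref, w)
            assert h[0, 0, 0, 0, 0] == pytest.approx(h_ref, abs=1e-12)
            assert c[0, 0, 0, 0, 0] == pytest.approx(c_ref, abs=1e-12)

    def test_state_shape_mismatch_rejected(self):
        cell = self._cell()
        x = np.zeros((1, 3, 4, 7, 2))
        with pytest.raises(ValueError):
            cell.step(x, np.zeros((1, 3, 4, 7, 5)), np.zeros((1, 3, 4, 7, 5)))


class TestBiConvLSTM3D:
    def test_output_channels_doubled(self):
        model = SeizurePredictor(tiny_config())
        seq = np.random.default_rng(0).standard_normal((2, 2, 3, 4, 7, 3))
        out = bi_convlstm3d_forward(seq, model.cell_fwd, model.cell_bwd)
        assert out.shape == (2, 3, 4, 7, 4)  # 2 + 2 hidden channels

    def test_reversal_symmetry(self):
        model = SeizurePredictor(tiny_config(seed=3))
        seq = np.random.default_rng(1).standard_normal((2, 2, 3, 4, 7, 3))
        fwd = bi_convlstm3d_forward(seq, model.cell_fwd, model.cell_bwd)
        swapped = bi_convlstm3d_forward(seq[:, ::-1], model.cell_bwd,
                                        model.cell_fwd)
        hd = model.config.convlstm_hidden
        assert np.allclose(fwd[..., :hd], swapped[..., hd:], atol=1e-12)
        assert np.allclose(fwd[..., hd:], swapped[..., :hd], atol=1e-12)

    def test_zero_weights_zero_output(self):
        model = SeizurePredictor(tiny_config())
        for cell in (model.cell_fwd, model.cell_bwd):
            for p in cell.params():
                p.value[...] = 0.0
        seq = np.random.default_rng(2).standard_normal((1, 2, 3, 4, 7, 3))
        out = bi_convlstm3d_forward(seq, model.cell_fwd, model.cell_bwd)
        assert np.all(out == 0.0)

    def test_empty_sequence_rejected(self):
        model = SeizurePredictor(tiny_config())
        with pytest.raises(ValueError):
            bi_convlstm3d_forward(np.zeros((1, 0, 3, 4, 7, 3)),
                                  model.cell_fwd, model.cell_bwd)


class TestSEAttention:
    def test_forced_identity_scaling(self):
        att = SEAttention3D(4, 2, np.random.default_rng(0))
        att.fc2.W.value[...] = 0.0
        att.fc2.b.value[...] = 500.0  # sigmoid saturates to exactly 1.0
        x = np.random.default_rng(1).standard_normal((2, 3, 4, 7, 4))
        assert np.array_equal(se_attention3d(x, att), x)

    def test_squeeze_of_constant_channel(self):
        att = SEAttention3D(4, 2, np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((2, 3, 4, 7, 4))
        x[:, :, :, :, 2] = 7.5
        _, cache = att.forward(x)
        s = cache[1]  # squeeze vector
        assert np.allclose(s[:, 2], 7.5, atol=1e-12)

    def test_channel_weights_in_unit_interval_and_contraction(self):
        att = SEAttention3D(8, 4, np.random.default_rng(2))
        x = np.random.default_rng(3).standard_normal((3, 3, 4, 7, 8))
        out, cache = att.forward(x)
        e = cache[4]
        assert np.all((e > 0) & (e < 1))
        in_norm = np.sqrt((x ** 2).sum(axis=(1, 2, 3)))
        out_norm = np.sqrt((out ** 2).sum(axis=(1, 2, 3)))
        assert np.all(out_norm <= in_norm + 1e-12)

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError):
            SEAttention3D(6, 4, np.random.default_rng(0))


class TestModelForward:
    def test_probabilities_sum_to_one(self):
        model = SeizurePredictor(tiny_config())
        x = np.random.default_rng(0).standard_normal((5, 2, 3, 4, 7, 1))
        probs = model_forward(model, x)
        assert probs.shape == (5, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_bit_stable(self):
        model = SeizurePredictor(tiny_config())
        x = np.random.default_rng(1).standard_normal((3, 2, 3, 4, 7, 1))
        assert np.array_equal(model_forward(model, x), model_forward(model, x))

    def test_temporal_order_sensitivity(self):
        """Swapping the two time steps must change the output for nearly all
        random weight draws."""
        x = np.random.default_rng(2).standard_normal((1, 2, 3, 4, 7, 1))
        changed = 0
        for seed in range(10):
            model = SeizurePredictor(tiny_config(seed=seed))
            a = model_forward(model, x)
            b = model_forward(model, x[:, ::-1])
            if not np.allclose(a, b, atol=1e-9):
                changed += 1
        assert changed >= 9

    def test_wrong_grid_rejected(self):
        model = SeizurePredictor(tiny_config())
        with pytest.raises(ValueError):
            model_forward(model, np.zeros((1, 2, 3, 5, 7, 1)))


class TestCountParameters:
    def test_reference_component_counts(self):
        counts = count_parameters(ModelConfig())
        assert counts["bi_convlstm3d"] == 2 * 4 * (256 * 256 + 256 * 256 + 256)
        assert counts["attention3d"] == 512 * 64 + 64 + 64 * 512 + 512

    def test_trivial_conv(self):
        rng = np.random.default_rng(0)
        conv = Conv3D(1, 1, (1, 1, 1), rng)
        assert sum(p.size for p in conv.params()) == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_formula_matches_instantiated_weights(self, seed):
        rng = np.random.default_rng(seed)
        hidden = int(rng.integers(1, 6))
        red_choices = [r for r in (1, 2) if (2 * hidden) % r == 0]
        cfg = ModelConfig(
            p3d_channels=tuple(int(c) for c in rng.integers(1, 7, size=4)),
            p3d_kernels=((1, 3, 3), (3, 1, 1)) * 2,
            bn_after_pairs=bool(rng.integers(0, 2)),
            convlstm_hidden=hidden,
            attention_channels=2 * hidden,
            attention_reduction=int(rng.choice(red_choices)),
            head_hidden=int(rng.integers(1, 8)),
            peephole=bool(rng.integers(0, 2)),
            seed=seed,
        )
        model = SeizurePredictor(cfg)
        assert count_parameters(cfg)["total"] == model.n_parameters()


class TestTraining:
    def _separable_data(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 2
        x = 0.3 * rng.standard_normal((n, 2, 3, 4, 7, 1))
        x += (2.0 * y - 1.0)[:, None, None, None, None, None]
        return x, y

    def test_learns_separable_data(self):
        x, y = self._separable_data()
        cfg = ModelConfig.reduced(epochs=10, batch_size=16, val_fraction=0.0,
                                  seed=1)
        model, history = pz.train(x, y, cfg)
        assert history[-1]["train_acc"] >= 0.95
        assert model.evaluate(x, y)[1] >= 0.95

    def test_loss_decreases_after_first_epoch(self):
        x, y = self._separable_data(seed=4)
        model = SeizurePredictor(tiny_config(val_fraction=0.0))
        init_loss, _ = model.evaluate(x, y)
        history = model.fit(x, y, epochs=1)
        final_loss, _ = model.evaluate(x, y)
        assert final_loss < init_loss

    def test_seeded_training_reproducible(self):
        x, y = self._separable_data(seed=5)
        cfg = tiny_config(epochs=1, dropout=0.25)
        _, h1 = pz.train(x, y, cfg)
        _, h2 = pz.train(x, y, cfg)
        assert h1[0]["train_loss"] == h2[0]["train_loss"]

    def test_single_class_rejected(self):
        x, _ = self._separable_data(n=10)
        with pytest.raises(ValueError):
            pz.train(x, np.ones(10, dtype=int), tiny_config())


def test_gradients_match_finite_differences():
    """Backprop through the full stack agrees with central differences at a
    generic parameter point (biases nudged off the ReLU kink at zero)."""
    cfg = tiny_config()
    model = SeizurePredictor(cfg)
    jitter = np.random.default_rng(9)
    for p in model.params():
        p.value += jitter.uniform(-0.05, 0.05, p.value.shape)
    x = np.random.default_rng(1).standard_normal((3, 2, 3, 4, 7, 1))
    y = np.array([0, 1, 1])
    _, dlogits, cache, _ = model.loss_and_grad(x, y, training=False)
    model.backward(dlogits, cache)
    rng = np.random.default_rng(2)
    for p in model.params():
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            eps = 1e-6
            orig = p.value[idx]
            p.value[idx] = orig + eps
            l1, _, _, _ = model.loss_and_grad(x, y, training=False)
            p.value[idx] = orig - eps
            l2, _, _, _ = model.loss_and_grad(x, y, training=False)
            p.value[idx] = orig
            num = (l1 - l2) / (2 * eps)
            assert abs(num - p.grad[idx]) < 1e-4 * max(1.0, abs(num))
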