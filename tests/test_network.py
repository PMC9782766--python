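"""Architecture contract, determinism, parameter arithmetic, gradient checks."""

import numpy as np
import pytest

from bdlseg.network import (
    NetworkConfig,
    build_model,
    load_checkpoint,
    predict_case,
    save_checkpoint,
)
from bdlseg.nn import Conv3d, InstanceNorm3d, UNet3D
from bdlseg.losses import soft_dice_loss, soft_dice_loss_grad


def conv_block_params(cin, cout, k):
    """Independent closed-form count: conv weights+bias plus norm gain+bias."""
    return (cout * cin * k**3 + cout) + 2 * cout


def unet_param_oracle(in_ch, f, depth):
    filt = [f * 2**l for l in range(depth)]
    total = conv_block_params(in_ch, filt[0], 3) + conv_block_params(filt[0], filt[0], 3)
    for l in range(1, depth):
        total += conv_block_params(filt[l - 1], filt[l], 3)  # strided down
        total += 2 * conv_block_params(filt[l], filt[l], 3)
    for l in range(depth - 1):
        total += conv_block_params(filt[l + 1], filt[l], 3)  # up conv
        total += conv_block_params(2 * filt[l], filt[l], 3)  # localization 3x3x3
        total += conv_block_params(filt[l], filt[l], 1)  # localization 1x1x1
    total += filt[0] * 1 + 1  # sigmoid head, no norm
    return total


class TestConfig:
    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(input_size=30, depth=3)

    def test_depth_and_filters_bounds(self):
        with pytest.raises(ValueError):
            NetworkConfig(depth=2)
        with pytest.raises(ValueError):
            NetworkConfig(base_filters=2)


class TestArchitecture:
    def test_output_shape_and_range(self):
        cfg = NetworkConfig(depth=3, base_filters=8, input_size=32, seed=0)
        model = build_model(cfg)
        x = np.random.default_rng(0).normal(size=(4, 32, 32, 32)).astype(np.float32)
        y = predict_case(model, x)
        assert y.shape == (32, 32, 32)
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_seeded_init_reproducible(self):
        cfg = NetworkConfig(depth=3, base_filters=4, input_size=16, seed=3)
        s1 = build_model(cfg).state_dict()
        s2 = build_model(cfg).state_dict()
        assert set(s1) == set(s2)
        for k in s1:
            assert np.array_equal(s1[k], s2[k])

    def test_inference_deterministic(self):
        cfg = NetworkConfig(depth=3, base_filters=4, input_size=16, seed=1)
        model = build_model(cfg)
        x = np.random.default_rng(1).normal(size=(4, 16, 16, 16)).astype(np.float32)
        y1 = predict_case(model, x)
        # interleave another case: instance norm -> no cross-case leakage
        predict_case(model, np.zeros_like(x) + 1.0)
        y2 = predict_case(model, x)
        assert np.array_equal(y1, y2)

    @pytest.mark.parametrize(
        "in_ch,f,depth", [(4, 8, 3), (4, 4, 3), (2, 4, 2), (4, 8, 4)]
    )
    def test_parameter_count_matches_oracle(self, in_ch, f, depth):
        model = UNet3D(in_channels=in_ch, base_filters=f, depth=depth, seed=0)
        assert model.n_params == unet_param_oracle(in_ch, f, depth)

    def test_wrong_channel_count_rejected(self):
        model = build_model(NetworkConfig(input_size=16, base_filters=4))
        with pytest.raises(ValueError, match="channels|expected"):
            predict_case(model, np.zeros((3, 16, 16, 16)))


class TestGradients:
    """Central finite-difference checks of the hand-derived backward passes."""

    def _fd_check(self, layer, x, n_probe=4, h=1e-6, rtol=1e-5):
        rng = np.random.default_rng(0)
        r = rng.normal(size=layer.forward(x).shape)
        dx = layer.backward(r.copy())
        flat_idx = rng.choice(x.size, size=n_probe, replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, x.shape)
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = ((layer.forward(xp) * r).sum() - (layer.forward(xm) * r).sum()) / (
                2 * h
            )
            assert dx[idx] == pytest.approx(fd, rel=rtol, abs=1e-7)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_conv3d_input_gradient(self, stride):
        rng = np.random.default_rng(1)
        layer = Conv3d(2, 3, k=3, stride=stride, rng=rng, dtype=np.float64)
        x = rng.normal(size=(2, 6, 6, 6))
        self._fd_check(layer, x)

    def test_conv3d_weight_gradient(self):
        rng = np.random.default_rng(2)
        layer = Conv3d(2, 2, k=3, rng=rng, dtype=np.float64)
        x = rng.normal(size=(2, 5, 5, 5))
        r = rng.normal(size=layer.forward(x).shape)
        layer.forward(x)
        layer.dw[...] = 0
        layer.backward(r.copy())
        h = 1e-6
        for idx in [(0, 0, 0, 0, 0), (1, 1, 2, 2, 2)]:
            orig = layer.w[idx]
            layer.w[idx] = orig + h
            fplus = (layer.forward(x) * r).sum()
            layer.w[idx] = orig - h
            fminus = (layer.forward(x) * r).sum()
            layer.w[idx] = orig
            fd = (fplus - fminus) / (2 * h)
            assert layer.dw[idx] == pytest.approx(fd, rel=1e-5)

    def test_instance_norm_gradient(self):
        rng = np.random.default_rng(3)
        layer = InstanceNorm3d(3, dtype=np.float64)
        layer.g[:] = rng.uniform(0.5, 1.5, 3)
        x = rng.normal(size=(3, 4, 4, 4))
        self._fd_check(layer, x, rtol=1e-4)

    def test_end_to_end_weight_gradients(self):
        # loss(model(x)) gradients on a tiny float64 net vs finite differences
        model = UNet3D(in_channels=2, base_filters=4, depth=2, seed=5,
                       dtype=np.float64)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(2, 8, 8, 8))
        t = (rng.random((8, 8, 8)) > 0.9).astype(np.float64)

        def loss():
            return soft_dice_loss(model.forward(x), t)

        loss_val = soft_dice_loss(model.forward(x), t)
        g = soft_dice_loss_grad(model.forward(x), t)
        for _, _, grad in model.parameters():
            grad[...] = 0.0
        model.forward(x)
        model.backward(g)
        params = model.parameters()
        h = 1e-6
        probes = [(0, 0), (len(params) // 2, 0), (len(params) - 1, 0)]
        for pi, offset in probes:
            name, val, grad = params[pi]
            flat = val.reshape(-1)
            orig = flat[offset]
            flat[offset] = orig + h
            lp = loss()
            flat[offset] = orig - h
            lm = loss()
            flat[offset] = orig
            fd = (lp - lm) / (2 * h)
            assert grad.reshape(-1)[offset] == pytest.approx(
                fd, rel=1e-4, abs=1e-9
            ), name


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        cfg = NetworkConfig(depth=3, base_filters=4, input_size=16, seed=2)
        model = build_model(cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(model, cfg, path)
        loaded, loaded_cfg = load_checkpoint(path)
        assert loaded_cfg == cfg
        x = np.random.default_rng(0).normal(size=(4, 16, 16, 16)).astype(np.float32)
        assert np.array_equal(predict_case(model, x), predict_case(loaded, x))

    def test_architecture_mismatch_refused(self, tmp_path):
        cfg = NetworkConfig(depth=3, base_filters=4, input_size=16, seed=2)
        model = build_model(cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(model, cfg, path)
        other = NetworkConfig(depth=3, base_filters=8, input_size=16, seed=2)
        with pytest.raises(ValueError, match="mismatch"):
            load_checkpoint(path, expect_cfg=other)
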