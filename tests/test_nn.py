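import numpy as np
import pytest

from protondl.nn import ops
from protondl.nn.autodiff import backward, constant, parameter
from protondl.nn.layers import BatchNorm3d, Conv3d, ConvBNReLU, DenseConvolve
from protondl.nn.model import (
    DESK_SCALE_CONFIG,
    HDUNet,
    ModelConfig,
    load_checkpoint,
    predict_volume,
    save_checkpoint,
)
from protondl.nn.optim import Adam


def numeric_grad(f, x, eps):
    """Central-difference gradient of scalar f with respect to array x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def check_op_grad(build, x_data, eps=5e-2, tol=2e-2):
    """Gradient-check an op: ``build(x_tensor)`` must return a Tensor.

    The loss is the op output dotted with fixed random coefficients, which is
    quadratic or piecewise-linear in the input, so wide central differences
    are exact up to float32 noise.
    """
    rng = np.random.default_rng(0)
    x = parameter(x_data.copy())
    out = build(x)
    coeff = rng.normal(size=out.data.shape).astype(np.float32)

    def f():
        x2 = constant(x.data)
        return float(np.sum(build(x2).data.astype(np.float64) * coeff))

    from protondl.nn.autodiff import Tensor

    scalar = Tensor(
        np.float32(np.sum(out.data.astype(np.float64) * coeff)), parents=(out,)
    )
    scalar.backward_fn = lambda g: out.accumulate(g * coeff)
    backward(scalar)
    num = numeric_grad(f, x.data, eps)
    denom = max(1.0, float(np.abs(num).max()))
    assert np.max(np.abs(x.grad - num)) / denom < tol


class TestOpGradients:
    def test_conv3d(self):
        rng = np.random.default_rng(1)
        w = parameter(rng.normal(0, 0.5, (3, 3, 3, 2, 3)).astype(np.float32))
        x_data = rng.normal(0, 1, (2, 4, 4, 4, 2)).astype(np.float32)
        check_op_grad(lambda x: ops.conv3d(x, w), x_data)

    def test_conv3d_strided(self):
        rng = np.random.default_rng(2)
        w = parameter(rng.normal(0, 0.5, (3, 3, 3, 2, 3)).astype(np.float32))
        x_data = rng.normal(0, 1, (1, 4, 4, 4, 2)).astype(np.float32)
        check_op_grad(lambda x: ops.conv3d(x, w, stride=(2, 2, 2)), x_data)

    def test_conv3d_weight_grad(self):
        rng = np.random.default_rng(3)
        x = constant(rng.normal(0, 1, (1, 4, 4, 2, 2)).astype(np.float32))
        w_data = rng.normal(0, 0.5, (3, 3, 1, 2, 2)).astype(np.float32)
        check_op_grad(lambda w: ops.conv3d(x, w), w_data)

    def test_relu(self):
        rng = np.random.default_rng(4)
        # keep values away from the kink
        x_data = rng.normal(0, 1, (2, 3, 3, 2, 2)).astype(np.float32)
        x_data[np.abs(x_data) < 0.2] = 0.5
        check_op_grad(ops.relu, x_data, eps=1e-2)

    def test_maxpool(self):
        rng = np.random.default_rng(5)
        x_data = rng.normal(0, 2, (1, 4, 4, 2, 2)).astype(np.float32)
        check_op_grad(lambda x: ops.maxpool3d(x, (2, 2, 2)), x_data, eps=1e-2)

    def test_upsample(self):
        rng = np.random.default_rng(6)
        x_data = rng.normal(0, 1, (1, 2, 2, 2, 3)).astype(np.float32)
        check_op_grad(lambda x: ops.upsample_nearest(x, (2, 2, 1)), x_data)

    def test_concat_and_slice(self):
        rng = np.random.default_rng(7)
        other = constant(rng.normal(0, 1, (1, 3, 3, 2, 2)).astype(np.float32))
        x_data = rng.normal(0, 1, (1, 3, 3, 2, 2)).astype(np.float32)
        check_op_grad(lambda x: ops.channel_slice(ops.concat([x, other]), 1, 3), x_data)

    def test_batchnorm_training_mode(self):
        rng = np.random.default_rng(8)
        gamma = parameter(np.array([1.3, 0.7], dtype=np.float32))
        beta = parameter(np.array([0.1, -0.2], dtype=np.float32))
        x_data = rng.normal(0, 1, (2, 3, 3, 2, 2)).astype(np.float32)

        def build(x):
            rm = np.zeros(2, dtype=np.float32)
            rv = np.ones(2, dtype=np.float32)
            return ops.batchnorm(x, gamma, beta, rm, rv, training=True)

        check_op_grad(build, x_data, eps=5e-2, tol=3e-2)

    def test_mse_loss_gradient(self):
        rng = np.random.default_rng(9)
        target = constant(rng.normal(size=(2, 8)).astype(np.float32))
        pred = parameter(rng.normal(size=(2, 8)).astype(np.float32))
        loss = ops.mse_loss(pred, target)
        backward(loss)
        expect = 2.0 * (pred.data - target.data) / pred.data.size
        assert np.allclose(pred.grad, expect, atol=1e-6)


class TestModelArchitecture:
    def test_channel_growth_arithmetic(self):
        cfg = DESK_SCALE_CONFIG
        model = HDUNet(cfg, np.random.default_rng(0))
        g, n = cfg.growth_rate, cfg.convs_per_block
        # encoder: each dense block adds n * growth; each downsample adds growth
        ch = cfg.in_channels + n * g
        for i in range(len(cfg.pool_schedule)):
            ch = ch + g + n * g
        # the deepest feature map has `ch` channels
        x = constant(np.zeros((1, *cfg.patch_shape, cfg.in_channels), dtype=np.float32))
        model.set_training(False)
        out = model(x)
        assert model.last_bottleneck_shape == (*cfg.bottleneck_shape, ch)
        assert out.data.shape == (1, *cfg.patch_shape, cfg.out_channels)

    def test_bottleneck_shape_property(self):
        assert DESK_SCALE_CONFIG.bottleneck_shape == (4, 4, 2)
        assert ModelConfig().bottleneck_shape == (8, 8, 1)

    def test_indivisible_patch_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(patch_shape=(30, 32, 8))

    def test_residual_model_starts_at_identity(self):
        model = HDUNet(DESK_SCALE_CONFIG, np.random.default_rng(1))
        model.set_training(False)
        rng = np.random.default_rng(2)
        x = np.abs(rng.normal(0, 1, (1, *DESK_SCALE_CONFIG.patch_shape, 2))).astype(
            np.float32
        )
        out = model(constant(x))
        assert np.allclose(out.data[..., 0], x[..., 0], atol=1e-6)

    def test_optimizer_step_decreases_loss(self):
        cfg = DESK_SCALE_CONFIG
        model = HDUNet(cfg, np.random.default_rng(3))
        model.set_training(True)
        opt = Adam(model.parameters(), lr=1e-3)
        rng = np.random.default_rng(4)
        x = constant(
            np.abs(rng.normal(0, 1, (1, *cfg.patch_shape, 2))).astype(np.float32)
        )
        y = constant(
            np.abs(rng.normal(0, 1, (1, *cfg.patch_shape, 1))).astype(np.float32)
        )
        losses = []
        for _ in range(3):
            opt.zero_grad()
            loss = ops.mse_loss(model(x), y)
            losses.append(float(loss.data))
            backward(loss)
            opt.step()
        assert losses[-1] < losses[0]

    def test_config_roundtrip(self):
        cfg = DESK_SCALE_CONFIG
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestCheckpoint:
    def test_roundtrip_bitexact_predictions(self, tmp_path):
        cfg = ModelConfig(
            growth_rate=4,
            pool_schedule=((2, 2, 2),),
            up_channels=8,
            patch_shape=(8, 8, 4),
        )
        model = HDUNet(cfg, np.random.default_rng(5))
        # push the running stats away from init so buffers are exercised
        model.set_training(True)
        rng = np.random.default_rng(6)
        x = constant(rng.normal(0, 1, (2, 8, 8, 4, 2)).astype(np.float32))
        model(x)
        model.set_training(False)
        ref = model(x).data
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.config == cfg
        out = loaded(x).data
        assert np.array_equal(out, ref)


class TestPredictVolume:
    def test_identityish_model_covers_volume(self):
        from protondl.grid import GridSpec, ScalarVolume

        cfg = ModelConfig(
            growth_rate=4,
            pool_schedule=((2, 2, 2),),
            up_channels=8,
            patch_shape=(8, 8, 4),
        )
        model = HDUNet(cfg, np.random.default_rng(7))  # residual zero-init head
        model.set_training(False)
        g = GridSpec((20, 20, 8), (2.0, 2.0, 2.5))
        rng = np.random.default_rng(8)
        pb = ScalarVolume(g, np.abs(rng.normal(1, 0.2, g.shape)), "normalized")
        ct = ScalarVolume(g, rng.random(g.shape), "normalized")
        out = predict_volume(model, pb, ct)
        # fresh residual model is the identity on the PB channel, so sliding
        # window + averaging must reproduce the input up to BN-eval noise
        assert np.allclose(out.values, pb.values, atol=1e-4)

    def test_restriction_keeps_pb_outside_treated_region(self):
        from protondl.grid import GridSpec, ScalarVolume

        cfg = ModelConfig(
            growth_rate=4,
            pool_schedule=((2, 2, 2),),
            up_channels=8,
            patch_shape=(8, 8, 4),
        )
        model = HDUNet(cfg, np.random.default_rng(7))
        # perturb the head so the model is NOT the identity
        model.set_training(False)
        for p in model.parameters():
            p.data += 0.01 * np.random.default_rng(1).normal(size=p.data.shape).astype(
                p.data.dtype
            )
        g = GridSpec((40, 40, 8), (2.0, 2.0, 2.5))
        vals = np.zeros(g.shape)
        vals[4:12, 4:12, 2:6] = 1.0  # compact treated region in one corner
        pb = ScalarVolume(g, vals, "normalized")
        ct = ScalarVolume(g, np.full(g.shape, 0.3), "normalized")
        out = predict_volume(model, pb, ct)
        # far from the treated region (beyond the half-patch margin) the PB
        # values pass through untouched
        assert np.array_equal(out.values[24:, 24:, :], pb.values[24:, 24:, :])
        # without restriction the whole canvas goes through the model
        full = predict_volume(model, pb, ct, restrict_to_treated=False)
        assert not np.array_equal(full.values[24:, 24:, :], pb.values[24:, 24:, :])

    def test_requires_normalized_inputs(self):
        from protondl.grid import GridSpec, ScalarVolume

        model = HDUNet(
            ModelConfig(
                growth_rate=4,
                pool_schedule=((2, 2, 2),),
                up_channels=8,
                patch_shape=(8, 8, 4),
            ),
            np.random.default_rng(9),
        )
        g = GridSpec((8, 8, 4), (2.0, 2.0, 2.5))
        dose = ScalarVolume(g, np.ones(g.shape), "dose_gy")
        norm = ScalarVolume(g, np.ones(g.shape), "normalized")
        with pytest.raises(ValueError):
            predict_volume(model, dose, norm)
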