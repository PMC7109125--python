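import numpy as np
import pytest

from canalseg import nn
from canalseg.errors import CanalSegError
from canalseg.models import (
    ModelSpec,
    SEGNET_PLAN,
    UNET2D_FEWER,
    UNET2D_ORIGINAL,
    build_model,
    describe_model,
    load_encoder_weights,
)

from oracles import unet_output_size

rng = np.random.default_rng(7)


def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.mark.parametrize(
    "factory,x_shape",
    [
        (lambda: nn.Conv(3, 4, 3, 2, "same", rng), (2, 3, 6, 6)),
        (lambda: nn.Conv(3, 4, 3, 2, "valid", rng), (2, 3, 6, 6)),
        (lambda: nn.Conv(2, 3, 3, 3, "valid", rng), (1, 2, 6, 6, 6)),
        (lambda: nn.BatchNorm(3), (2, 3, 6, 6)),
        (lambda: nn.MaxPool(2), (2, 3, 6, 6)),
        (lambda: nn.MaxPool(3), (1, 2, 6, 6, 6)),
        (lambda: nn.UpConv(3, 2, 2, rng), (2, 3, 6, 6)),
        (lambda: nn.UpConv(2, 2, 3, rng), (1, 2, 6, 6, 6)),
    ],
    ids=["conv2d-same", "conv2d-valid", "conv3d-valid", "batchnorm", "pool2d", "pool3d", "upconv2d", "upconv3d"],
)
def test_layer_gradients_match_finite_differences(factory, x_shape):
    layer = factory()
    x = rng.normal(size=x_shape)
    y = layer.forward(x.copy(), train=True)
    R = rng.normal(size=y.shape)

    def loss():
        return float((layer.forward(x.copy(), train=True) * R).sum())

    layer.forward(x.copy(), train=True)
    dx = layer.backward(R.copy())
    gx = _num_grad(loss, x)
    assert np.abs(dx - gx).max() <= 1e-6 * max(1.0, np.abs(gx).max())
    for p in layer.params():
        p.grad[...] = 0.0
        layer.forward(x.copy(), train=True)
        layer.backward(R.copy())
        analytic = p.grad.copy()
        numeric = _num_grad(loss, p.value)
        assert np.abs(analytic - numeric).max() <= 1e-6 * max(1.0, np.abs(numeric).max())


def test_weighted_cross_entropy_gradient():
    logits = rng.normal(size=(2, 2, 5, 5))
    target = (rng.random((2, 5, 5)) > 0.7).astype(float)
    ce = nn.WeightedCrossEntropy((5.3, 1000.0))
    loss, grad = ce.loss_and_grad(logits, target)
    numeric = _num_grad(lambda: ce.loss_and_grad(logits, target)[0], logits)
    assert np.abs(grad - numeric).max() <= 1e-6 * np.abs(numeric).max()


def test_unet_end_to_end_gradient():
    spec = ModelSpec("unet2d", filters=(3, 4, 6), batch_norm=False, dropout=False, seed=2)
    _, net = build_model(spec, (8, 8))
    x = rng.normal(size=(2, 1, 8, 8))
    t = (rng.random((2, 8, 8)) > 0.8).astype(float)
    ce = nn.WeightedCrossEntropy((1.0, 3.0))

    def loss():
        return ce.loss_and_grad(net.forward(x.copy(), train=True), t)[0]

    for q in net.params():
        q.grad[...] = 0.0
    _, g = ce.loss_and_grad(net.forward(x.copy(), train=True), t)
    net.backward(g)
    p = net.params()[0]
    numeric = _num_grad(loss, p.value)
    assert np.abs(p.grad - numeric).max() <= 1e-5 * np.abs(numeric).max()


class TestShapes:
    def test_same_padding_unet_preserves_256(self):
        desc = describe_model(ModelSpec("unet2d"), (256, 256))
        assert desc.output_spatial == (256, 256)
        assert all(
            r.spatial == (256, 256) for r in desc.layers if r.name.startswith(("enc0", "final"))
        )

    def test_valid_3d_unet_matches_recurrence_oracle_at_132(self):
        desc = describe_model(ModelSpec("unet3d"), (132, 132, 132))
        expected = unet_output_size(132, depth=3, valid=True)
        assert desc.output_spatial == (expected,) * 3

    @pytest.mark.parametrize("size", [100, 140, 164])
    def test_valid_3d_sizes_follow_oracle(self, size):
        try:
            expected = unet_output_size(size, depth=3, valid=True)
        except AssertionError:
            with pytest.raises(CanalSegError):
                describe_model(ModelSpec("unet3d"), (size,) * 3)
            return
        desc = describe_model(ModelSpec("unet3d"), (size,) * 3)
        assert desc.output_spatial == (expected,) * 3

    def test_incompatible_size_error_names_layer(self):
        with pytest.raises(CanalSegError, match="pool|conv"):
            describe_model(ModelSpec("unet3d"), (20, 20, 21))

    def test_adjacent_slice_input_only_changes_first_conv(self):
        d1 = describe_model(ModelSpec("unet2d"), (64, 64))
        d5 = describe_model(ModelSpec("unet2d", input_channels=5), (64, 64))
        assert [r.spatial for r in d1.layers] == [r.spatial for r in d5.layers]
        diff = [(a, b) for a, b in zip(d1.layers, d5.layers) if a.n_params != b.n_params]
        assert len(diff) == 1 and diff[0][0].name == "enc0.conv0"
        assert d5.layers[0].n_params - d1.layers[0].n_params == 4 * 64 * 9

    def test_instantiated_forward_shape_matches_description(self):
        spec = ModelSpec("unet3d", filters=(2, 3), seed=3)
        desc, net = build_model(spec, (20, 20, 20))
        y = net.forward(rng.normal(size=(1, 1, 20, 20, 20)), train=True)
        assert y.shape[2:] == desc.output_spatial
        assert y.shape[1] == 2


class TestParameterCounts:
    def test_tiny_unet2d_hand_count(self):
        # conv params = Cout*Cin*9 + Cout; upconv = Cin*Cout*4 + Cout
        spec = ModelSpec("unet2d", filters=(4, 8), batch_norm=False, dropout=False)
        desc, net = build_model(spec, (8, 8))
        hand = (
            (4 * 1 * 9 + 4) + (4 * 4 * 9 + 4)  # encoder level
            + (8 * 4 * 9 + 8) + (8 * 8 * 9 + 8)  # bottleneck
            + (8 * 4 * 4 + 4)  # up-conv
            + (4 * 8 * 9 + 4) + (4 * 4 * 9 + 4)  # decoder level
            + (2 * 4 * 1 + 2)  # final 1x1
        )
        assert desc.total_params == hand
        assert sum(p.value.size for p in net.params()) == hand

    def test_tiny_unet3d_hand_count(self):
        spec = ModelSpec("unet3d", filters=(2, 3))
        desc, net = build_model(spec)
        hand = (
            (2 * 1 * 27 + 2) + 2 * 2 + (2 * 2 * 27 + 2) + 2 * 2
            + (3 * 2 * 27 + 3) + 2 * 3 + (3 * 3 * 27 + 3) + 2 * 3
            + (3 * 2 * 8 + 2)
            + (2 * 4 * 27 + 2) + 2 * 2 + (2 * 2 * 27 + 2) + 2 * 2
            + (2 * 2 * 1 + 2)
        )
        assert desc.total_params == hand
        assert sum(p.value.size for p in net.params()) == hand

    def test_tiny_segnet_hand_count(self):
        spec = ModelSpec("segnet2d", filters=((2, 2), (3, 3)))
        desc, net = build_model(spec)
        enc = (2 * 1 * 9 + 2) + 4 + (2 * 2 * 9 + 2) + 4
        enc += (3 * 2 * 9 + 3) + 6 + (3 * 3 * 9 + 3) + 6
        dec = (3 * 3 * 9 + 3) + 6 + (2 * 3 * 9 + 2) + 4
        dec += (2 * 2 * 9 + 2) + 4 + (2 * 2 * 9 + 2) + 4
        final = 2 * 2 * 1 + 2
        assert desc.total_params == enc + dec + final
        assert sum(p.value.size for p in net.params()) == enc + dec + final

    def test_canonical_plans(self):
        assert describe_model(ModelSpec("unet2d", filters=UNET2D_FEWER)).total_params < describe_model(
            ModelSpec("unet2d", filters=UNET2D_ORIGINAL)
        ).total_params
        assert len(SEGNET_PLAN) == 5 and sum(len(s) for s in SEGNET_PLAN) == 13


class TestSpecInvariants:
    def test_unet3d_rejects_dropout_and_same_padding(self):
        with pytest.raises(CanalSegError):
            ModelSpec("unet3d", dropout=True).resolved()
        with pytest.raises(CanalSegError):
            ModelSpec("unet3d", padding="same").resolved()

    def test_segnet_requires_batch_norm(self):
        with pytest.raises(CanalSegError):
            ModelSpec("segnet2d", batch_norm=False).resolved()

    def test_unet2d_variant_is_same_padding(self):
        with pytest.raises(CanalSegError):
            ModelSpec("unet2d", padding="valid").resolved()


def test_encoder_weight_loading_round_trip(tmp_path):
    spec = ModelSpec("unet2d", filters=(3, 4), batch_norm=False, dropout=False, seed=5)
    _, net = build_model(spec)
    saved = {name: p.value.copy() for name, p in net.param_items()}
    np.savez(tmp_path / "w.npz", **saved)
    for p in net.params():
        p.value[...] = 0.0
    loaded = load_encoder_weights(net, str(tmp_path / "w.npz"))
    assert set(loaded) == set(saved)
    for name, p in net.param_items():
        np.testing.assert_array_equal(p.value, saved[name])
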