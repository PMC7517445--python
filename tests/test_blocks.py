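"""Attention, dense/residual and bottleneck blocks against scripted oracles."""

import numpy as np
import pytest

from acaunet.blocks import (
    ACAUBlock,
    DAC,
    DenseBlock,
    RMP,
    ResidualBlock,
    SqueezeExcite,
    excitation_gate,
    gem_pool,
    squeeze_excite,
    squeeze_gap,
)
from acaunet.grad import Tensor, nn
from conftest import naive_conv2d, numgrad


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


# ------------------------------------------------------------------ squeeze/gap

def test_squeeze_gap_examples(rng):
    const = np.full((1, 2, 4, 4), 3.0, np.float32)
    np.testing.assert_allclose(squeeze_gap(const).data, [[3.0, 3.0]])
    x = np.array([1.0, 2.0, 3.0, 4.0], np.float32).reshape(1, 1, 2, 2)
    np.testing.assert_allclose(squeeze_gap(x).data, [[2.5]])
    # GAP is GeM at pk = 1 on non-negative input
    r = np.abs(rng.normal(size=(2, 3, 5, 5))).astype(np.float32)
    np.testing.assert_allclose(squeeze_gap(r).data, gem_pool(r, 1.0).data, rtol=1e-6)


def test_excitation_gate_zero_weights_give_half():
    v = np.array([[0.3, -1.2, 4.0]], np.float32)
    w1 = np.zeros((3, 3), np.float32)
    w2 = np.zeros((3, 3), np.float32)
    np.testing.assert_allclose(excitation_gate(v, w1, w2).data, 0.5)


def test_excitation_gate_matches_brute_force(rng):
    v = rng.normal(size=(2, 3)).astype(np.float32)
    w1 = rng.normal(size=(3, 3)).astype(np.float32)  # r = 1
    w2 = rng.normal(size=(3, 3)).astype(np.float32)
    got = excitation_gate(v, w1, w2).data
    want = _sigmoid(np.maximum(v @ w1.T, 0.0) @ w2.T)
    np.testing.assert_allclose(got, want, rtol=1e-5)
    assert np.all((got > 0) & (got < 1))


def test_excitation_gate_rejects_bad_shapes():
    with pytest.raises(ValueError, match="bottleneck"):
        excitation_gate(np.zeros((1, 4), np.float32),
                        np.zeros((2, 3), np.float32), np.zeros((4, 2), np.float32))


def test_squeeze_excite_loop_oracle(rng):
    x = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
    w1 = rng.normal(size=(3, 3)).astype(np.float32)
    w2 = rng.normal(size=(3, 3)).astype(np.float32)
    got = squeeze_excite(x, w1, w2).data
    want = np.empty_like(x)
    for n in range(2):
        v = [x[n, c].mean() for c in range(3)]
        gate = _sigmoid(np.maximum(np.asarray(v) @ w1.T, 0.0) @ w2.T)
        for c in range(3):
            want[n, c] = x[n, c] * gate[c]
    np.testing.assert_allclose(got, want, rtol=1e-5)


def test_se_gating_shrinks_but_never_flips_sign(rng):
    x = rng.normal(size=(2, 4, 5, 5)).astype(np.float32)
    se = SqueezeExcite(4, reduction=2, rng=rng)
    y = se(Tensor(x)).data
    assert np.all(np.abs(y) <= np.abs(x) + 1e-7)
    assert np.all(np.sign(y) * np.sign(x) >= 0)


def test_se_reduction_must_divide_channels(rng):
    with pytest.raises(ValueError, match="does not divide"):
        SqueezeExcite(6, reduction=4, rng=rng)


# ------------------------------------------------------------------------- GeM

def test_gem_pool_limits_and_examples():
    x = np.array([1.0, 2.0, 3.0, 4.0], np.float32).reshape(1, 1, 2, 2)
    np.testing.assert_allclose(gem_pool(x, 1.0).data, [[2.5]])  # average pooling
    np.testing.assert_allclose(gem_pool(x, 2.0).data, [[np.sqrt(30.0 / 4.0)]],
                               rtol=1e-5)
    # large pk approaches max pooling; with a unique max the exact gap is
    # max * (1 - (1/N)^(1/pk)), so the 1e-3 band needs a repeated max
    assert gem_pool(x, 100.0).data[0, 0] > 3.9
    twin_max = np.array([4.0, 4.0, 2.0, 1.0], np.float32).reshape(1, 1, 2, 2)
    np.testing.assert_allclose(gem_pool(twin_max, 1000.0).data, [[4.0]], rtol=1e-3)


def test_gem_pool_monotone_in_exponent(rng):
    x = np.abs(rng.normal(size=(1, 3, 6, 6))).astype(np.float32)
    values = [gem_pool(x, pk).data for pk in (1.0, 2.0, 3.0, 5.0, 10.0)]
    for lo, hi in zip(values[:-1], values[1:]):
        assert np.all(hi >= lo - 1e-5)


def test_gem_pool_precondition_errors(rng):
    neg = rng.normal(size=(1, 1, 3, 3)).astype(np.float32)
    neg[0, 0, 0, 0] = -1.0
    with pytest.raises(ValueError, match="non-negative"):
        gem_pool(neg, 2.5)
    with pytest.raises(ValueError, match="pk must be >= 1"):
        gem_pool(np.abs(neg), 0.5)


# ---------------------------------------------------------------- dense blocks

def test_dense_block_channel_arithmetic(rng):
    for c_in, n_layers, growth in [(8, 3, 4), (4, 1, 2), (16, 2, 8)]:
        block = DenseBlock(c_in, n_layers, growth, bn_size=2, norm="none", rng=rng)
        assert block.out_channels == c_in + n_layers * growth
        x = Tensor(rng.normal(size=(1, c_in, 4, 4)).astype(np.float32))
        out = block(x)
        assert out.shape == (1, block.out_channels, 4, 4)


def test_dense_block_rejects_wrong_width(rng):
    block = DenseBlock(8, 1, 4, norm="none", rng=rng)
    with pytest.raises(ValueError, match="built for 8 channels"):
        block(Tensor(np.zeros((1, 5, 4, 4), np.float32)))


def test_one_layer_dense_block_is_concat_of_input_and_layer(rng):
    block = DenseBlock(3, 1, 2, bn_size=2, norm="none", rng=rng)
    x = Tensor(rng.normal(size=(1, 3, 4, 4)).astype(np.float32))
    out = block(x).data
    np.testing.assert_allclose(out[:, :3], x.data)  # the dense wiring passes u0
    h1 = block.layer0(x).data
    np.testing.assert_allclose(out[:, 3:], h1, rtol=1e-6)
    assert np.abs(h1).max() > 0  # concatenation is not a no-op


def test_dense_block_matches_scripted_convolution_oracle(rng):
    """Layer l must see [u0, ..., u_{l-1}]; verified with a loop-conv oracle."""
    block = DenseBlock(2, 2, 2, bn_size=1, norm="none", rng=rng)
    x = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
    feats = x
    for i in range(2):
        layer = getattr(block, f"layer{i}")
        w1 = layer.body._layers[2].weight.data  # 1x1 bottleneck conv
        w3 = layer.body._layers[5].weight.data  # 3x3 conv
        h = naive_conv2d(np.maximum(feats, 0.0), w1)
        u = naive_conv2d(np.maximum(h, 0.0), w3, padding=1)
        feats = np.concatenate([feats, u], axis=1)
    got = block(Tensor(x)).data
    np.testing.assert_allclose(got, feats, rtol=1e-4, atol=1e-5)


def test_dense_block_gradient_flows_through_both_paths(rng):
    """On a 1x1 map, u0 reaches the output directly and through H1."""
    block = DenseBlock(2, 1, 2, bn_size=1, norm="none", rng=rng)
    # strictly positive input so the layer's leading rectifier stays open
    x = Tensor(np.abs(rng.normal(size=(1, 2, 1, 1))).astype(np.float32) + 0.1,
               requires_grad=True)
    out = block(x)
    out[:, 2:].sum().backward()  # only the H1 half of the concatenation
    through_h1 = x.grad.copy()
    assert np.abs(through_h1).max() > 0

    def f():
        return float(block(Tensor(x.data)).data[:, 2:].sum())

    num = numgrad(f, x.data)
    np.testing.assert_allclose(through_h1, num, rtol=2e-2, atol=1e-4)

    x.grad = None
    block(x)[:, :2].sum().backward()  # the direct path is the identity
    np.testing.assert_allclose(x.grad, np.ones_like(x.data), atol=1e-6)


# -------------------------------------------------------------- residual block

def test_residual_block_identities(rng):
    conv = nn.Conv2d(3, 3, 3, padding=1, rng=rng)
    block = ResidualBlock(conv)
    x = rng.normal(size=(1, 3, 5, 5)).astype(np.float32)
    out = block(Tensor(x)).data
    np.testing.assert_allclose(out - conv(Tensor(x)).data, x, rtol=1e-5, atol=1e-6)

    conv.weight.data[:] = 0.0
    conv.bias.data[:] = 0.0
    np.testing.assert_allclose(block(Tensor(x)).data, x)  # H == 0 -> identity

    zero = np.zeros_like(x)
    np.testing.assert_allclose(block(Tensor(zero)).data, conv(Tensor(zero)).data)


def test_residual_block_rejects_shape_change(rng):
    block = ResidualBlock(nn.Conv2d(3, 4, 1, rng=rng))
    with pytest.raises(ValueError, match="changed shape"):
        block(Tensor(np.zeros((1, 3, 4, 4), np.float32)))


# ------------------------------------------------------------------------ ACAU

@pytest.fixture()
def acau(rng):
    return ACAUBlock(low_channels=2, high_channels=3, out_channels=4,
                     se_reduction=1, pk=5.0, norm="none", rng=rng)


def test_acau_attention_matches_scripted_pipeline(acau, rng):
    """Step-by-step numpy evaluation of squeeze/excite/GeM/gating."""
    x_low = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
    x_high = rng.normal(size=(1, 3, 2, 2)).astype(np.float32)

    v_l = x_low.mean(axis=(2, 3))
    gate = _sigmoid(np.maximum(v_l @ acau.se.fc1.weight.data.T, 0.0)
                    @ acau.se.fc2.weight.data.T)
    y_l = x_low * gate[:, :, None, None]
    h = naive_conv2d(x_high, acau.match.weight.data, acau.match.bias.data)
    h = np.maximum(h, 0.0)
    v_h = (h**5.0).mean(axis=(2, 3)) ** (1.0 / 5.0)
    want = y_l * _sigmoid(v_h)[:, :, None, None]

    got = acau.attention(Tensor(x_low), Tensor(x_high)).data
    np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-5)


def test_acau_zero_skip_annihilates_attention(acau):
    x_low = np.zeros((1, 2, 4, 4), np.float32)
    x_high = np.random.default_rng(0).normal(size=(1, 3, 2, 2)).astype(np.float32)
    assert np.all(acau.attention(Tensor(x_low), Tensor(x_high)).data == 0)


def test_acau_gates_forced_open_reduce_to_identity(rng):
    """With both sigmoid gates pinned at 1, the attention path passes x_low."""
    acau = ACAUBlock(2, 3, 4, se_reduction=1, pk=1.0, norm="none", rng=rng)
    # saturate the SE gate: huge positive second-layer weights
    acau.se.fc1.weight.data[:] = 0.0
    acau.se.fc2.weight.data[:] = 0.0
    # saturate the GeM gate: huge positive bias on the channel-matching conv
    acau.match.weight.data[:] = 0.0
    acau.match.bias.data[:] = 50.0
    x_low = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
    x_high = rng.normal(size=(1, 3, 2, 2)).astype(np.float32)
    got = acau.attention(Tensor(x_low), Tensor(x_high)).data
    np.testing.assert_allclose(got, 0.5 * x_low, rtol=1e-4)  # SE gate = sigmoid(0)
    assert np.allclose(_sigmoid(50.0), 1.0)


def test_acau_forward_upsamples_to_skip_resolution(acau, rng):
    x_low = Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32))
    x_high = Tensor(rng.normal(size=(1, 3, 2, 2)).astype(np.float32))
    out = acau(x_low, x_high)
    assert out.shape == (1, 4, 4, 4)


def test_acau_rejects_incompatible_resolutions(acau):
    with pytest.raises(ValueError, match="not 2x"):
        acau(Tensor(np.zeros((1, 2, 6, 6), np.float32)),
             Tensor(np.zeros((1, 3, 2, 2), np.float32)))


# ------------------------------------------------------------------- DAC / RMP

def test_dac_zero_weights_reduce_to_identity(rng):
    dac = DAC(3, (1, 3, 5), rng=rng)
    for i in range(3):
        branch = getattr(dac, f"branch{i}")
        branch.weight.data[:] = 0.0
        branch.bias.data[:] = 0.0
    x = rng.normal(size=(1, 3, 6, 6)).astype(np.float32)
    np.testing.assert_allclose(dac(Tensor(x)).data, x)


def test_dac_preserves_spatial_size(rng):
    dac = DAC(4, (1, 3, 5), rng=rng)
    x = Tensor(rng.normal(size=(2, 4, 7, 7)).astype(np.float32))
    assert dac(x).shape == x.shape


def test_rmp_adds_one_channel_per_pool_size(rng):
    x = Tensor(np.abs(np.random.default_rng(3).normal(size=(1, 5, 12, 12))
                      ).astype(np.float32))
    rmp = RMP(5, (2, 3, 5, 6), rng=rng)
    out = rmp(x)
    assert out.shape == (1, 5 + 4, 12, 12)
    np.testing.assert_allclose(out.data[:, :5], x.data)  # input passes through


def test_rmp_pool_larger_than_extent_raises(rng):
    rmp = RMP(2, (2, 3, 5, 6), rng=rng)
    with pytest.raises(ValueError, match="exceeds spatial extent"):
        rmp(Tensor(np.zeros((1, 2, 4, 4), np.float32)))


# ------------------------------------------------------------------ properties

def test_blocks_map_finite_inputs_to_finite_outputs():
    """Random inputs over many seeds never produce NaN/Inf."""
    for seed in range(100):
        r = np.random.default_rng(seed)
        x = Tensor(r.normal(size=(1, 4, 8, 8)).astype(np.float32) * 3.0)
        build_rng = np.random.default_rng(seed + 1)
        block = DenseBlock(4, 2, 4, norm="instance", rng=build_rng)
        se = SqueezeExcite(4, 2, rng=build_rng)
        dac = DAC(4, (1, 3), rng=build_rng)
        for module in (block, se, dac):
            assert np.all(np.isfinite(module(x).data))
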