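import itertools

import numpy as np
import pytest

from cayolo import attention as A
from cayolo.nn import tensor as T

from conftest import seeded_map
from oracles import (oracle_cam, oracle_channel_attention,
                     oracle_channel_shuffle, oracle_spatial_attention)


# -------------------------------------------------------------------------
# channel shuffle
# -------------------------------------------------------------------------

class TestChannelShuffle:
    def test_identity_with_one_group(self):
        x = np.arange(4)[:, None, None] * np.ones((1, 3, 3))
        assert np.array_equal(A.channel_shuffle(x, 1), x)

    def test_c4_g2_permutation(self):
        x = np.arange(4)[:, None, None] * np.ones((1, 2, 2))
        out = A.channel_shuffle(x, 2)
        assert np.array_equal(out[:, 0, 0], [0, 2, 1, 3])

    def test_matches_bruteforce_permutation(self, rng):
        for c in (2, 4, 6, 8, 12):
            x = rng.normal(size=(c, 2, 2))
            for g in (d for d in range(1, c + 1) if c % d == 0):
                assert np.array_equal(A.channel_shuffle(x, g),
                                      oracle_channel_shuffle(x, g))

    @pytest.mark.parametrize("c", [2, 4, 6, 8, 12])
    def test_roundtrip_and_bijection(self, c, rng):
        x = rng.normal(size=(c, 2, 2))
        for g in (d for d in range(1, c + 1) if c % d == 0):
            out = A.channel_shuffle(x, g)
            # multiset of channel slices conserved
            assert sorted(map(tuple, out.reshape(c, -1))) == \
                sorted(map(tuple, x.reshape(c, -1)))
            # (g, C/g) round trip restores the input
            assert np.array_equal(A.channel_shuffle(out, c // g), x)

    def test_rejects_bad_groups(self):
        x = np.zeros((4, 2, 2))
        with pytest.raises(ValueError, match="divide"):
            A.channel_shuffle(x, 3)
        with pytest.raises(ValueError, match=">= 1"):
            A.channel_shuffle(x, 0)

    def test_spatial_values_untouched(self, rng):
        x = rng.normal(size=(6, 4, 5))
        out = A.channel_shuffle(x, 3)
        perm = A.shuffle_permutation(6, 3)
        for k, p in enumerate(perm):
            assert np.array_equal(out[k], x[p])

    def test_gradient_flows_through(self):
        x = T.Tensor(np.arange(8.0).reshape(2, 2, 2), requires_grad=True)
        out = A.channel_shuffle(x, 2)
        out.sum().backward()
        assert np.array_equal(x.grad, np.ones((2, 2, 2)))


# -------------------------------------------------------------------------
# SGAM channel attention
# -------------------------------------------------------------------------

def _zeroed(block):
    for p in block.parameters():
        p.data[:] = 0
    return block


class TestChannelAttention:
    def test_zero_params_give_half_gate(self, rng):
        block = _zeroed(A.ChannelAttention(4, ratio=2, dtype=np.float64))
        x = rng.normal(size=(4, 5, 5))
        ac, out = A.sgam_channel_attention(x, block)
        assert np.allclose(ac, 0.5)
        assert np.allclose(out, 0.5 * x)

    def test_shape_preserved(self, rng):
        block = A.ChannelAttention(6, ratio=3, dtype=np.float64)
        x = rng.normal(size=(6, 3, 7))
        ac, out = A.sgam_channel_attention(x, block)
        assert out.shape == x.shape and ac.shape == x.shape

    def test_weights_strictly_in_unit_interval(self, rng):
        block = A.ChannelAttention(8, dtype=np.float64)
        ac, _ = A.sgam_channel_attention(rng.normal(size=(8, 4, 4)), block)
        assert np.all(ac > 0) and np.all(ac < 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_straightline_oracle(self, seed):
        rng = np.random.default_rng(seed)
        block = A.ChannelAttention(3, ratio=2, rng=rng, dtype=np.float64)
        block.fc1.bias.data[:] = rng.normal(size=block.fc1.bias.shape)
        block.fc2.bias.data[:] = rng.normal(size=block.fc2.bias.shape)
        x = seeded_map(seed + 500, 3, 4, 4)
        ac, out = A.sgam_channel_attention(x, block)
        ac_o, out_o = oracle_channel_attention(
            x, block.fc1.weight.data, block.fc1.bias.data,
            block.fc2.weight.data, block.fc2.bias.data)
        np.testing.assert_allclose(ac, ac_o, atol=1e-6)
        np.testing.assert_allclose(out, out_o, atol=1e-6)

    def test_rejects_channel_mismatch(self, rng):
        block = A.ChannelAttention(4, dtype=np.float64)
        with pytest.raises(ValueError, match="channel mismatch"):
            block(rng.normal(size=(5, 3, 3)))


# -------------------------------------------------------------------------
# SGAM spatial attention
# -------------------------------------------------------------------------

class TestSpatialAttention:
    def test_zero_params_give_half_gate(self, rng):
        block = _zeroed(A.SpatialAttention(4, ratio=2, groups=2,
                                           dtype=np.float64))
        block.bn.gamma.data[:] = 1.0  # BN identity
        block.eval()
        x = rng.normal(size=(4, 6, 6))
        a_s, out = A.sgam_spatial_attention(x, block)
        assert np.allclose(a_s, 0.5)
        assert np.allclose(out, 0.5 * x)

    def test_group1_equals_unshuffled_product(self, rng):
        block = A.SpatialAttention(4, ratio=2, groups=1, dtype=np.float64)
        block.eval()
        x = rng.normal(size=(4, 5, 5))
        a_s, out = A.sgam_spatial_attention(x, block)
        np.testing.assert_allclose(out, x * a_s, atol=1e-12)

    def test_rejects_non7_kernel(self):
        with pytest.raises(ValueError, match="7x7"):
            A.SpatialAttention(4, k=3)

    def test_rejects_bad_groups(self):
        with pytest.raises(ValueError, match="divide"):
            A.SpatialAttention(4, groups=3)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_straightline_oracle(self, seed):
        rng = np.random.default_rng(seed + 40)
        block = A.SpatialAttention(4, ratio=2, groups=2, rng=rng,
                                   dtype=np.float64)
        block.eval()  # running-stats BN: identity at init
        x = seeded_map(seed + 900, 4, 8, 8)
        a_s, out = A.sgam_spatial_attention(x, block)
        a_o, out_o = oracle_spatial_attention(
            x, block.conv1.weight.data, block.conv1.bias.data,
            block.bn.gamma.data, block.bn.beta.data,
            block.bn.running_mean, block.bn.running_var, block.bn.eps,
            block.conv2.weight.data, block.conv2.bias.data, 2)
        np.testing.assert_allclose(a_s, a_o, atol=1e-5)
        np.testing.assert_allclose(out, out_o, atol=1e-5)

    def test_bounds(self, rng):
        block = A.SpatialAttention(4, dtype=np.float64)
        block.eval()
        a_s, _ = A.sgam_spatial_attention(rng.normal(size=(4, 7, 7)), block)
        assert np.all(a_s > 0) and np.all(a_s < 1)


# -------------------------------------------------------------------------
# SGAM composition
# -------------------------------------------------------------------------

class TestSGAM:
    def test_zero_params_quarter_gate(self, rng):
        block = _zeroed(A.SGAM(4, ratio=2, groups=2, dtype=np.float64))
        block.sa.bn.gamma.data[:] = 1.0
        block.eval()
        x = rng.normal(size=(4, 6, 6))
        out = A.sgam_forward(x, block)
        np.testing.assert_allclose(out, 0.25 * x, atol=1e-12)

    def test_zero_input_zero_output(self):
        block = A.SGAM(4, dtype=np.float64)
        block.eval()
        out = A.sgam_forward(np.zeros((4, 5, 5)), block)
        assert np.allclose(out, 0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_composed_oracles(self, seed):
        rng = np.random.default_rng(seed + 77)
        block = A.SGAM(4, ratio=2, groups=2, rng=rng, dtype=np.float64)
        block.eval()
        x = seeded_map(seed + 1300, 4, 6, 6)
        out = A.sgam_forward(x, block)
        _, xca = oracle_channel_attention(
            x, block.ca.fc1.weight.data, block.ca.fc1.bias.data,
            block.ca.fc2.weight.data, block.ca.fc2.bias.data)
        _, out_o = oracle_spatial_attention(
            xca, block.sa.conv1.weight.data, block.sa.conv1.bias.data,
            block.sa.bn.gamma.data, block.sa.bn.beta.data,
            block.sa.bn.running_mean, block.sa.bn.running_var,
            block.sa.bn.eps,
            block.sa.conv2.weight.data, block.sa.conv2.bias.data, 2)
        np.testing.assert_allclose(out, out_o, atol=1e-5)

    def test_shape_preserved_batched(self, rng):
        block = A.SGAM(8, dtype=np.float64)
        block.eval()
        x = T.Tensor(rng.normal(size=(2, 8, 5, 5)))
        assert block(x).shape == (2, 8, 5, 5)


# -------------------------------------------------------------------------
# CAM
# -------------------------------------------------------------------------

class TestCAM:
    def test_zero_input_zero_output(self, rng):
        block = A.CAM(4, dtype=np.float64)
        for p in block.parameters():  # even with random biases
            if p.ndim == 1:
                p.data[:] = rng.normal(size=p.shape)
        out = A.cam_forward(np.zeros((4, 6, 6)), block)
        assert np.allclose(out, 0.0)

    def test_softmax_normalizes_per_channel(self, rng):
        block = A.CAM(4, dtype=np.float64)
        w = block.spatial_softmax(T.astensor(rng.normal(size=(4, 5, 5))))
        sums = w.data.reshape(4, -1).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_residual_structure(self, rng):
        block = A.CAM(4, ratio=2, dtype=np.float64)
        x = rng.normal(size=(4, 5, 5))
        out = A.cam_forward(x, block)
        w = block.spatial_softmax(T.astensor(x)).data
        enhancement = out - x
        # the enhancement term is gate * (softmax * x): bounded by |softmax*x|
        assert np.all(np.abs(enhancement) <= np.abs(w * x) + 1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_straightline_oracle(self, seed):
        rng = np.random.default_rng(seed + 11)
        block = A.CAM(2, ratio=1, rng=rng, dtype=np.float64)
        for p in (block.conv_ctx.bias, block.conv_a.bias, block.conv_b.bias):
            p.data[:] = rng.normal(size=p.shape)
        x = seeded_map(seed + 1700, 2, 4, 4)
        out = A.cam_forward(x, block)
        out_o = oracle_cam(
            x, block.conv_ctx.weight.data, block.conv_ctx.bias.data,
            block.conv_a.weight.data, block.conv_a.bias.data,
            block.ln.gamma.data, block.ln.beta.data, block.ln.eps,
            block.conv_b.weight.data, block.conv_b.bias.data)
        np.testing.assert_allclose(out, out_o, atol=1e-6)

    def test_shape_preserved(self, rng):
        block = A.CAM(8, dtype=np.float64)
        x = rng.normal(size=(8, 3, 9))
        assert A.cam_forward(x, block).shape == x.shape


# -------------------------------------------------------------------------
# cross-block invariants
# -------------------------------------------------------------------------

@pytest.mark.parametrize("kind", ["cam", "sgam"])
def test_block_factory_and_finiteness(kind, rng):
    block = A.build_block({"type": kind, "ratio": 2, "groups": 2}, 8,
                          dtype=np.float64)
    block.eval()
    x = rng.normal(size=(8, 6, 6)) * 10
    out = block(T.astensor(x))
    assert out.shape == (8, 6, 6)
    assert np.all(np.isfinite(out.data))


def test_block_factory_rejects_unknown():
    with pytest.raises(ValueError, match="unknown attention block"):
        A.build_block({"type": "cbam"}, 8)


@pytest.mark.parametrize("kind", ["cam", "sgam"])
def test_finite_difference_gradient(kind):
    rng = np.random.default_rng(5)
    block = A.build_block({"type": kind, "ratio": 2, "groups": 2}, 4,
                          rng=rng, dtype=np.float64)
    block.eval()
    x = T.Tensor(rng.normal(size=(4, 5, 5)), requires_grad=True)
    (block(x) ** 2.0).sum().backward()
    ana = x.grad[1, 2, 3]
    eps = 1e-6

    def value(v):
        x2 = x.data.copy()
        x2[1, 2, 3] = v
        return float((block(T.Tensor(x2)) ** 2.0).sum().data)

    num = (value(x.data[1, 2, 3] + eps) - value(x.data[1, 2, 3] - eps)) / (2 * eps)
    assert abs(num - ana) <= 1e-3 * max(1.0, abs(num))
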