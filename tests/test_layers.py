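"""SE / SE-GRU attention and the convolutional block variants.

The GRU and SE-GRU paths are checked against independent brute-force
transcriptions of the gate equations written with plain Python loops, so a
silent switch to a different recurrence convention would be caught.
"""

import math

import numpy as np
import pytest

from dsrunet.nn.autodiff import Tensor
from dsrunet.nn.layers import (
    GRUCell, PlainBlock, ResidualBlock, SEBlock, SEGRUBlock,
    SparseResidualBlock, gru_step, se_apply, squeeze,
)


def _sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


def gru_oracle(x_t, h_prev, Wr, Wz, W, br, bz, b):
    """Literal loop transcription of the reset/update-gate equations."""
    B, H = h_prev.shape
    out = np.zeros((B, H))
    for n in range(B):
        hx = list(h_prev[n]) + list(x_t[n])
        r = [_sigmoid(sum(hx[k] * Wr[k, j] for k in range(len(hx))) + br[j])
             for j in range(H)]
        z = [_sigmoid(sum(hx[k] * Wz[k, j] for k in range(len(hx))) + bz[j])
             for j in range(H)]
        rhx = [r[j] * h_prev[n, j] for j in range(H)] + list(x_t[n])
        h_tilde = [math.tanh(sum(rhx[k] * W[k, j] for k in range(len(rhx))) + b[j])
                   for j in range(H)]
        out[n] = [(1 - z[j]) * h_prev[n, j] + z[j] * h_tilde[j] for j in range(H)]
    return out


def se_gru_oracle(x, cell: GRUCell, proj_w, proj_b):
    """squeeze -> GRU scan over channels -> scalar projection -> sigmoid."""
    B, C, L = x.shape
    z = x.mean(axis=2)
    s = np.zeros((B, C))
    h = np.zeros((B, cell.hidden_size))
    for t in range(C):
        h = gru_oracle(z[:, t:t + 1], h, cell.W_r.data, cell.W_z.data,
                       cell.W.data, cell.b_r.data, cell.b_z.data, cell.b.data)
        s[:, t] = [
            _sigmoid(float(h[n] @ proj_w[:, 0]) + proj_b[0]) for n in range(B)
        ]
    return s


class TestGRUStep:
    def _zero_params(self, I, H):
        shape = (H + I, H)
        zeros = lambda s: Tensor(np.zeros(s))
        return [zeros(shape)] * 3 + [zeros(H)] * 3

    def test_all_zero_params_zero_state(self):
        params = self._zero_params(3, 2)
        h = gru_step(Tensor(np.ones((4, 3))), Tensor(np.zeros((4, 2))), *params)
        np.testing.assert_allclose(h.data, 0.0)

    def test_all_zero_params_halves_state(self):
        # z = 0.5 and h~ = 0, so h_t = 0.5 * h_prev
        params = self._zero_params(3, 2)
        h_prev = np.array([[1.0, -2.0], [0.5, 4.0]])
        h = gru_step(Tensor(np.zeros((2, 3))), Tensor(h_prev), *params)
        np.testing.assert_allclose(h.data, 0.5 * h_prev)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        I, H, B = 3, 2, 4
        cell = GRUCell(I, H, rng)
        x = rng.normal(size=(B, I))
        h0 = rng.normal(size=(B, H))
        ours = cell.step(Tensor(x), Tensor(h0)).data
        ref = gru_oracle(x, h0, cell.W_r.data, cell.W_z.data, cell.W.data,
                         cell.b_r.data, cell.b_z.data, cell.b.data)
        np.testing.assert_allclose(ours, ref, atol=1e-6)


class TestSqueezeAndApply:
    def test_squeeze_examples(self):
        x = Tensor(np.array([[[1.0, 3.0], [-2.0, 2.0]]]))  # [1,2,2]
        np.testing.assert_allclose(squeeze(x).data, [[2.0, 0.0]])
        const = Tensor(np.full((2, 3, 7), 4.5))
        np.testing.assert_allclose(squeeze(const).data, 4.5)
        single = Tensor(np.arange(6.0).reshape(2, 3, 1))
        np.testing.assert_allclose(squeeze(single).data, single.data[:, :, 0])

    def test_apply_identity_zero_and_general(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(2, 3, 5)))
        np.testing.assert_array_equal(
            se_apply(x, Tensor(np.ones((2, 3)))).data, x.data
        )
        np.testing.assert_allclose(
            se_apply(x, Tensor(np.zeros((2, 3)))).data, 0.0
        )
        s = rng.uniform(0.1, 2.0, size=(2, 3))
        y = se_apply(x, Tensor(s)).data
        for n in range(2):
            for c in range(3):
                np.testing.assert_allclose(y[n, c], x.data[n, c] * s[n, c])


class TestSEGRU:
    def test_matches_brute_force_composition(self):
        rng = np.random.default_rng(3)
        blk = SEGRUBlock(channels=8, reduction=4, rng=rng)
        x = Tensor(rng.normal(size=(2, 8, 16)))
        s = blk.weights(x).data
        ref = se_gru_oracle(x.data, blk.gru, blk.proj.weight.data, blk.proj.bias.data)
        np.testing.assert_allclose(s, ref, atol=1e-6)
        assert np.all((s > 0) & (s < 1))

    def test_channel_order_sensitivity(self):
        rng = np.random.default_rng(4)
        blk = SEGRUBlock(channels=8, reduction=4, rng=rng)
        x = rng.normal(size=(1, 8, 16))
        s_fwd = blk.weights(Tensor(x)).data[0]
        s_rev = blk.weights(Tensor(x[:, ::-1, :].copy())).data[0]
        # a feed-forward excitation would satisfy s_rev == s_fwd reversed
        assert not np.allclose(s_rev, s_fwd[::-1], atol=1e-6)

    def test_projection_bias_saturates_weights_to_one(self):
        rng = np.random.default_rng(5)
        blk = SEGRUBlock(channels=4, reduction=2, rng=rng)
        blk.proj.bias.data[...] = 50.0
        s = blk.weights(Tensor(rng.normal(size=(3, 4, 10)))).data
        np.testing.assert_allclose(s, 1.0, atol=1e-12)

    def test_reduction_must_divide_channels(self):
        with pytest.raises(ValueError, match="divide"):
            SEGRUBlock(channels=6, reduction=4)
        with pytest.raises(ValueError, match="divide"):
            SEBlock(channels=6, reduction=4)


class TestBlocks:
    def _zero_convs(self, block):
        for name in ("conv1", "conv2"):
            conv = getattr(block, name, None)
            if conv is not None:
                conv.weight.data[...] = 0.0
                conv.bias.data[...] = 0.0

    def test_sparse_encoder_reduces_to_identity(self):
        rng = np.random.default_rng(6)
        blk = SparseResidualBlock(4, 4, variant="encoder", rng=rng)
        self._zero_convs(blk)
        x = np.abs(rng.normal(size=(2, 4, 8)))  # nonnegative for ReLU
        out = blk(Tensor(x)).data
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_sparse_decoder_single_skip(self):
        rng = np.random.default_rng(7)
        blk = SparseResidualBlock(4, 4, variant="decoder", rng=rng)
        self._zero_convs(blk)
        x = np.abs(rng.normal(size=(2, 4, 8)))
        np.testing.assert_allclose(blk(Tensor(x)).data, x, atol=1e-12)
        assert not hasattr(blk, "conv2")

    def test_ordinary_residual_with_zero_f_is_activation(self):
        rng = np.random.default_rng(8)
        blk = ResidualBlock(4, 4, rng=rng)
        blk.conv2.weight.data[...] = 0.0
        blk.conv2.bias.data[...] = 0.0
        blk.bn2.beta.data[...] = 0.0
        x = rng.normal(size=(2, 4, 8))
        np.testing.assert_allclose(blk(Tensor(x)).data, np.maximum(x, 0.0), atol=1e-12)

    @pytest.mark.parametrize("cls,kw", [
        (PlainBlock, {}),
        (ResidualBlock, {}),
        (SparseResidualBlock, {"variant": "encoder"}),
        (SparseResidualBlock, {"variant": "decoder"}),
    ])
    def test_blocks_preserve_length_and_map_channels(self, cls, kw):
        rng = np.random.default_rng(9)
        blk = cls(3, 6, rng=rng, **kw)
        out = blk(Tensor(rng.normal(size=(2, 3, 16))))
        assert out.shape == (2, 6, 16)
        assert np.all(np.isfinite(out.data))
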