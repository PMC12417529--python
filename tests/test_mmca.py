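"""MMCA: tokenization, biased attention, grouped cascade vs slow oracle."""

import numpy as np
import pytest

from trilightnet.autodiff import Tensor
from trilightnet.mmca import (
    Mmca,
    biased_attention,
    featuremap_from_tokens,
    tokens_from_featuremap,
)

from _utils import cast_model_f64

rng = np.random.default_rng(99)


class TestTokenization:
    def test_shape_arithmetic(self):
        f = Tensor(rng.standard_normal((1, 4, 2, 2, 2)))
        assert tokens_from_featuremap(f).shape == (1, 8, 4)

    def test_bijection(self):
        f = rng.standard_normal((2, 5, 3, 4, 3))
        tokens = tokens_from_featuremap(Tensor(f))
        back = featuremap_from_tokens(tokens, (3, 4, 3))
        assert np.array_equal(back.data, f)

    def test_row_major_token_index(self):
        d, h, w = 3, 4, 5
        f = np.zeros((1, 2, d, h, w))
        for dd in range(d):
            for hh in range(h):
                for ww in range(w):
                    f[0, 0, dd, hh, ww] = (dd * h + hh) * w + ww
        tokens = tokens_from_featuremap(Tensor(f)).data
        assert np.array_equal(tokens[0, :, 0], np.arange(d * h * w))


class TestBiasedAttention:
    def test_zero_query_uniform_weights(self):
        L, dk = 6, 4
        v = rng.standard_normal((1, dk, L))
        out = biased_attention(
            Tensor(np.zeros((1, dk, L))),
            Tensor(rng.standard_normal((1, dk, L))),
            Tensor(v),
            Tensor(np.zeros((L, L))),
        )
        expected = np.repeat(v.mean(axis=2)[:, None, :], L, axis=1)
        assert np.abs(out.data - expected).max() < 1e-12

    def test_single_position(self):
        out = biased_attention(
            Tensor(rng.standard_normal((2, 3, 1))),
            Tensor(rng.standard_normal((2, 3, 1))),
            Tensor(rng.standard_normal((2, 3, 1))),
            Tensor(rng.standard_normal((1, 1))),
        )
        assert out.shape == (2, 1, 3)

    def test_softmax_closed_form(self):
        """Logits [0, ln2, ln3] normalize to [1/6, 1/3, 1/2]."""
        from trilightnet.autodiff import softmax

        w = softmax(Tensor(np.log([1.0, 2.0, 3.0])), axis=-1).data
        assert np.abs(w - np.array([1 / 6, 1 / 3, 1 / 2])).max() < 1e-12

    def test_rows_sum_to_one_extreme_logits(self):
        L, dk = 5, 2
        q = Tensor(rng.standard_normal((1, dk, L)))
        k = Tensor(rng.standard_normal((1, dk, L)))
        bias = Tensor(rng.choice([-1e4, 0.0, 1e4], size=(L, L)))
        from trilightnet.autodiff import matmul, softmax, transpose

        scores = matmul(transpose(q, (0, 2, 1)), k) * (1 / np.sqrt(dk)) + bias
        weights = softmax(scores, axis=-1).data
        assert np.abs(weights.sum(-1) - 1.0).max() < 1e-6
        assert np.all(np.isfinite(weights))

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            biased_attention(
                Tensor(np.full((1, 2, 3), np.inf)),
                Tensor(np.zeros((1, 2, 3))),
                Tensor(np.zeros((1, 2, 3))),
                Tensor(np.zeros((3, 3))),
            )


def mmca_slow_reference(x, y, mod):
    """Explicit-loop reference: groups, cascade, both directions."""

    def attn(q, k, v, bias):
        dk = q.shape[0]
        scores = q.T @ k / np.sqrt(dk) + bias
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        w = e / e.sum(axis=-1, keepdims=True)
        return w @ v.T  # [L, dk]

    B, L, C = x.shape
    N = mod.groups
    dk = mod.d_k
    zx = np.zeros((B, L, C))
    zy = np.zeros((B, L, C))
    for b in range(B):
        xt = x[b].T  # [C, L]
        yt = y[b].T
        prev_x = prev_y = None
        outs_x, outs_y = [], []
        for i in range(N):
            gp = mod.group_params[i]
            gx = xt[i * dk : (i + 1) * dk].copy()
            gy = yt[i * dk : (i + 1) * dk].copy()
            if prev_x is not None:
                gx += prev_x
                gy += prev_y
            qx, kx, vx = gp.qx.data @ gx, gp.kx.data @ gx, gp.vx.data @ gx
            qy, ky, vy = gp.qy.data @ gy, gp.ky.data @ gy, gp.vy.data @ gy
            ax = attn(qy, kx, vx, gp.bias.data)
            ay = attn(qx, ky, vy, gp.bias.data)
            prev_x, prev_y = ax.T, ay.T
            outs_x.append(ax)
            outs_y.append(ay)
        zx[b] = np.concatenate(outs_x, axis=1) @ mod.proj_x.weight.data.T + mod.proj_x.bias.data
        zy[b] = np.concatenate(outs_y, axis=1) @ mod.proj_y.weight.data.T + mod.proj_y.bias.data
    return np.concatenate([zx, zy], axis=-1)


class TestMmcaForward:
    @pytest.mark.parametrize("groups,b,l,c", [(1, 1, 4, 8), (2, 2, 8, 16), (4, 2, 6, 16)])
    def test_matches_slow_reference(self, groups, b, l, c):
        mod = cast_model_f64(Mmca(c, l, groups, rng=np.random.default_rng(groups)))
        x = rng.standard_normal((b, l, c))
        y = rng.standard_normal((b, l, c))
        out = mod(Tensor(x), Tensor(y))
        assert np.abs(out.data - mmca_slow_reference(x, y, mod)).max() < 1e-6

    def test_output_shape_contract(self):
        mod = Mmca(16, 6, 4, rng=np.random.default_rng(0))
        out = mod(
            Tensor(rng.standard_normal((3, 6, 16)).astype(np.float32)),
            Tensor(rng.standard_normal((3, 6, 16)).astype(np.float32)),
        )
        assert out.shape == (3, 6, 32)

    def test_symmetry_with_tied_parameters(self):
        """X = Y with x/y projections tied makes both fused halves equal."""
        mod = cast_model_f64(Mmca(8, 5, 2, rng=np.random.default_rng(1)))
        for gp in mod.group_params:
            gp.qy.data = gp.qx.data.copy()
            gp.ky.data = gp.kx.data.copy()
            gp.vy.data = gp.vx.data.copy()
        mod.proj_y.weight.data = mod.proj_x.weight.data.copy()
        mod.proj_y.bias.data = mod.proj_x.bias.data.copy()
        x = rng.standard_normal((2, 5, 8))
        out = mod(Tensor(x), Tensor(x.copy())).data
        assert np.array_equal(out[..., :8], out[..., 8:])

    def test_token_permutation_equivariance(self):
        """Permuting both inputs' tokens and conjugating every bias by
        the same permutation permutes the output tokens identically."""
        l = 6
        mod = cast_model_f64(Mmca(8, l, 2, rng=np.random.default_rng(2)))
        x = rng.standard_normal((1, l, 8))
        y = rng.standard_normal((1, l, 8))
        base = mod(Tensor(x), Tensor(y)).data
        perm = np.random.default_rng(3).permutation(l)
        for gp in mod.group_params:
            gp.bias.data = gp.bias.data[np.ix_(perm, perm)]
        permuted = mod(Tensor(x[:, perm]), Tensor(y[:, perm])).data
        assert np.abs(permuted - base[:, perm]).max() < 1e-10

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError):
            Mmca(10, 4, 4)

    def test_token_length_mismatch_rejected(self):
        mod = Mmca(8, 4, 2)
        with pytest.raises(ValueError):
            mod(
                Tensor(np.zeros((1, 4, 8), dtype=np.float32)),
                Tensor(np.zeros((1, 5, 8), dtype=np.float32)),
            )
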