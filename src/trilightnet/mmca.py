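"""MultiModal Cascaded Attention (MMCA).

Fuses two token streams (the HBAM-refined MRI and PET feature maps,
flattened to [B, L, C]) with grouped, cascaded, bidirectional
cross-attention.  Channels are split into N groups of width d_k = C/N;
within group i each modality attends to the other's queries:

    v^x_i = Attention(q^y_i, k^x_i, v^x_i)
    v^y_i = Attention(q^x_i, k^y_i, v^y_i)

with scores softmax(q^T k / sqrt(d_k) + b_i) where b_i is a learnable
L x L position-aware bias shared by both directions of group i.  The
cascade feeds each modality's attended output of group i-1 into its
own channel slice of group i before projection (same-modality
cascading).  Group outputs are concatenated and projected per modality,
and the final fused representation is concat(Z_x, Z_y) along channels,
shape [B, L, 2C].
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, matmul, softmax, transpose
from .nn import Linear, Module, ModuleList

__all__ = ["tokens_from_featuremap", "featuremap_from_tokens", "biased_attention", "Mmca"]


def tokens_from_featuremap(f: Tensor) -> Tensor:
    """[B, C, D, H, W] -> [B, L, C] with L = D*H*W tokens in row-major
    (D, H, W) order: token (d, h, w) sits at position (d*H + h)*W + w."""
    b, c = f.shape[:2]
    l = int(np.prod(f.shape[2:]))
    return transpose(f.reshape(b, c, l), (0, 2, 1))


def featuremap_from_tokens(tokens: Tensor, spatial: tuple[int, int, int]) -> Tensor:
    """Inverse of :func:`tokens_from_featuremap`."""
    b, l, c = tokens.shape
    if int(np.prod(spatial)) != l:
        raise ValueError(f"spatial {spatial} incompatible with L={l}")
    return transpose(tokens, (0, 2, 1)).reshape(b, c, *spatial)


def biased_attention(q: Tensor, k: Tensor, v: Tensor, bias: Tensor) -> Tensor:
    """Scaled dot-product attention with an additive L x L bias.

    q, k, v: [B, d_k, L] (channels-first, as produced by the group
    split); bias: [L, L].  Returns the attended values [B, L, d_k].
    Softmax rows are normalized with max subtraction, so they sum to 1
    even for extreme logits.
    """
    d_k = q.shape[-2]
    if not (np.all(np.isfinite(q.data)) and np.all(np.isfinite(k.data)) and np.all(np.isfinite(v.data))):
        raise ValueError("non-finite attention inputs")
    scores = matmul(transpose(q, (0, 2, 1)), k) * (1.0 / np.sqrt(d_k)) + bias
    weights = softmax(scores, axis=-1)  # [B, L, L]
    return matmul(weights, transpose(v, (0, 2, 1)))  # [B, L, d_k]


class _GroupParams(Module):
    """Per-group q/k/v channel maps for both modalities plus the shared
    positional bias."""

    def __init__(self, d_k: int, l_tokens: int, bias_init: float, rng, dtype=np.float32):
        super().__init__()
        bound = np.sqrt(6.0 / d_k)

        def cmap():
            return Tensor(
                rng.uniform(-bound, bound, (d_k, d_k)).astype(dtype), requires_grad=True
            )

        self.qx, self.kx, self.vx = cmap(), cmap(), cmap()
        self.qy, self.ky, self.vy = cmap(), cmap(), cmap()
        self.bias = Tensor(
            np.full((l_tokens, l_tokens), bias_init, dtype=dtype), requires_grad=True
        )


class Mmca(Module):
    def __init__(
        self,
        channels: int,
        l_tokens: int,
        groups: int = 4,
        bias_init: float = 0.0,
        rng=None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if channels % groups != 0:
            raise ValueError(f"C={channels} not divisible by N={groups} groups")
        self.channels = channels
        self.l_tokens = l_tokens
        self.groups = groups
        self.d_k = channels // groups
        self.group_params = ModuleList(
            [_GroupParams(self.d_k, l_tokens, bias_init, rng) for _ in range(groups)]
        )
        self.proj_x = Linear(channels, channels, rng=rng)
        self.proj_y = Linear(channels, channels, rng=rng)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        if x.shape != y.shape:
            raise ValueError(f"modality shapes differ: {x.shape} vs {y.shape}")
        b, l, c = x.shape
        if l != self.l_tokens or c != self.channels:
            raise ValueError(
                f"expected [B, {self.l_tokens}, {self.channels}] tokens, got {x.shape}"
            )
        xt = transpose(x, (0, 2, 1))  # [B, C, L]
        yt = transpose(y, (0, 2, 1))
        d_k = self.d_k
        outs_x: list[Tensor] = []
        outs_y: list[Tensor] = []
        prev_x = prev_y = None
        for i, gp in enumerate(self.group_params):
            gx = xt[:, i * d_k : (i + 1) * d_k, :]
            gy = yt[:, i * d_k : (i + 1) * d_k, :]
            if prev_x is not None:  # cascade: add previous attended output
                gx = gx + prev_x
                gy = gy + prev_y
            att_x = biased_attention(
                matmul(gp.qy, gy), matmul(gp.kx, gx), matmul(gp.vx, gx), gp.bias
            )
            att_y = biased_attention(
                matmul(gp.qx, gx), matmul(gp.ky, gy), matmul(gp.vy, gy), gp.bias
            )
            prev_x = transpose(att_x, (0, 2, 1))  # back to [B, d_k, L]
            prev_y = transpose(att_y, (0, 2, 1))
            outs_x.append(att_x)
            outs_y.append(att_y)
        z_x = self.proj_x(concatenate(outs_x, axis=-1))
        z_y = self.proj_y(concatenate(outs_y, axis=-1))
        return concatenate([z_x, z_y], axis=-1)  # [B, L, 2C]
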