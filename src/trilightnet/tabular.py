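"""Clinical tabular encoder: one KAN layer followed by PoolFormer blocks.

The seven standardized clinical features pass through a single
Kolmogorov-Arnold layer whose edge functions are
``phi(x) = w_b * SiLU(x) + w_s * sum_r c_r B_r(x)`` on a uniform cubic
B-spline grid, producing a latent vector that is reshaped into a short
token sequence and refined by ``M`` PoolFormer blocks:

    H'_m = H_{m-1} + AvgPool(LayerNorm(H_{m-1}))
    H_m  = H'_m   + MLP(LayerNorm(H'_m))

The token mixer is a kernel-3, stride-1 average pool along the token
axis that averages only existing neighbours (no identity subtraction —
the residual form above is used literally).  Setting ``use_kan=False``
swaps the KAN layer for a plain linear-plus-SiLU layer (the MLP
ablation) without touching anything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate, gelu, matmul, silu
from .nn import LayerNorm, Linear, Module, ModuleList
from .splines import SplineGrid, bspline_basis_tensor

__all__ = ["TabularConfig", "KanLayer", "PoolFormerBlock", "TabularEncoder"]


@dataclass(frozen=True)
class TabularConfig:
    in_dim: int = 7
    d_tab: int = 64
    tokens: int = 8
    channels: int = 8
    blocks: int = 2
    grid_size: int = 5
    spline_order: int = 3
    grid_range: tuple[float, float] = (-2.0, 2.0)
    mlp_expansion: int = 4
    use_kan: bool = True
    kan_layers: int = 1

    def __post_init__(self):
        if self.tokens * self.channels != self.d_tab:
            raise ValueError(
                f"d_tab={self.d_tab} must factor as tokens x channels "
                f"({self.tokens} x {self.channels})"
            )
        if self.blocks < 0 or self.kan_layers < 1:
            raise ValueError("blocks must be >= 0 and kan_layers >= 1")


class KanLayer(Module):
    """One Kolmogorov-Arnold layer.

    out_j = sum_i [ w_b[j,i] * SiLU(x_i)
                    + w_s[j,i] * sum_r c[j,i,r] * B_r(x_i) ]   (no bias)
    """

    def __init__(self, in_dim: int, out_dim: int, grid: SplineGrid, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.grid = grid
        bound = np.sqrt(6.0 / in_dim)
        self.base_weight = Tensor(
            rng.uniform(-bound, bound, (out_dim, in_dim)).astype(dtype), requires_grad=True
        )
        self.spline_weight = Tensor(
            rng.uniform(-bound, bound, (out_dim, in_dim)).astype(dtype), requires_grad=True
        )
        self.spline_coeffs = Tensor(
            (0.1 * rng.standard_normal((out_dim, in_dim, grid.n_basis))).astype(dtype),
            requires_grad=True,
        )

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"expected input dim {self.in_dim}, got {x.shape[-1]}")
        basis = bspline_basis_tensor(x, self.grid)  # [B, in, R]
        b = x.shape[0]
        r = self.grid.n_basis
        base = matmul(silu(x), self.base_weight.transpose())
        effective = self.spline_weight.reshape(self.out_dim, self.in_dim, 1) * self.spline_coeffs
        spline = matmul(
            basis.reshape(b, self.in_dim * r),
            effective.reshape(self.out_dim, self.in_dim * r).transpose(),
        )
        return base + spline


class LinearSiLU(Module):
    """Plain linear-plus-activation stand-in for the KAN layer (ablation)."""

    def __init__(self, in_dim: int, out_dim: int, rng=None):
        super().__init__()
        self.linear = Linear(in_dim, out_dim, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.linear(silu(x))


def _neighbor_avgpool(tokens: Tensor) -> Tensor:
    """Kernel-3 stride-1 average pool along the token axis, averaging
    only the neighbours that exist (counts 2 at the ends, 3 inside)."""
    b, t, c = tokens.shape
    if t == 1:
        return tokens
    zeros = Tensor(np.zeros((b, 1, c), dtype=tokens.data.dtype))
    left = concatenate([zeros, tokens[:, :-1, :]], axis=1)
    right = concatenate([tokens[:, 1:, :], zeros], axis=1)
    counts = np.full((1, t, 1), 3.0, dtype=tokens.data.dtype)
    counts[0, 0, 0] = counts[0, -1, 0] = 2.0
    return (tokens + left + right) * Tensor(1.0 / counts)


class PoolFormerBlock(Module):
    def __init__(self, channels: int, expansion: int = 4, rng=None):
        super().__init__()
        self.ln1 = LayerNorm(channels)
        self.ln2 = LayerNorm(channels)
        self.fc1 = Linear(channels, channels * expansion, rng=rng)
        self.fc2 = Linear(channels * expansion, channels, rng=rng)

    def forward(self, tokens: Tensor) -> Tensor:
        if tokens.ndim != 3:
            raise ValueError("PoolFormer block expects [B, T, C] tokens")
        h = tokens + _neighbor_avgpool(self.ln1(tokens))
        return h + self.fc2(gelu(self.fc1(self.ln2(h))))


class TabularEncoder(Module):
    """7 clinical features -> latent vector of length ``d_tab``."""

    def __init__(self, config: TabularConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        lo, hi = config.grid_range
        grid = SplineGrid(order=config.spline_order, grid_size=config.grid_size, lo=lo, hi=hi)
        dims = [config.in_dim] + [config.d_tab] * config.kan_layers
        if config.use_kan:
            self.kan = ModuleList(
                [KanLayer(dims[i], dims[i + 1], grid, rng) for i in range(config.kan_layers)]
            )
        else:
            self.kan = ModuleList(
                [LinearSiLU(dims[i], dims[i + 1], rng) for i in range(config.kan_layers)]
            )
        self.blocks = ModuleList(
            [PoolFormerBlock(config.channels, config.mlp_expansion, rng) for _ in range(config.blocks)]
        )

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.kan:
            h = layer(h)
        b = h.shape[0]
        tokens = h.reshape(b, self.config.tokens, self.config.channels)
        for block in self.blocks:
            tokens = block(tokens)
        return tokens.reshape(b, self.config.d_tab)
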