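"""Hybrid Block Attention Module (HBAM).

Refines an imaging feature map with clinical information in two gated
steps.  The hybrid channel attention adds a linear embedding of the
clinical latent vector to the CBAM-style channel-attention logits:

    M_hc = sigmoid( MLP(GAP(F)) + MLP(GMP(F)) + Embed(F_cli) )
    F_hc = M_hc (x) F                          (broadcast over space)

and the spatial attention then gates locations using a 7x7x7
convolution over the channel-mean and channel-max maps:

    M_s   = sigmoid( conv( [mean_c F_hc ; max_c F_hc] ) )
    F_out = M_s (x) F_hc                       (broadcast over channels)

Both gates lie in (0, 1), so the output is an elementwise shrinkage of
the input: signs are preserved and magnitudes never grow.  With a zero
clinical embedding the module reduces exactly to CBAM.  Information
flows clinical -> image only; the clinical vector itself is not
refined here.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, relu, sigmoid
from .nn import Conv3d, Linear, Module

__all__ = ["Hbam"]


class Hbam(Module):
    """One HBAM instance (each imaging branch gets its own weights)."""

    def __init__(
        self,
        c_cli: int,
        c_img: int,
        reduction: int = 8,
        spatial_kernel: int = 7,
        rng=None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if c_img % reduction != 0:
            raise ValueError(f"reduction {reduction} must divide C_img {c_img}")
        self.c_img = c_img
        self.embed = Linear(c_cli, c_img, rng=rng)
        # shared channel MLP; final layer bias-free so a zero-weight MLP
        # yields exactly sigmoid(0) = 0.5 gates
        self.mlp_fc1 = Linear(c_img, c_img // reduction, rng=rng)
        self.mlp_fc2 = Linear(c_img // reduction, c_img, bias=False, rng=rng)
        self.spatial_conv = Conv3d(
            2, 1, spatial_kernel, padding=spatial_kernel // 2, rng=rng
        )

    # -- pieces --------------------------------------------------------
    def embed_clinical(self, f_cli: Tensor) -> Tensor:
        """Linear projection of the clinical latent vector to C_img."""
        return self.embed(f_cli)

    def _channel_mlp(self, v: Tensor) -> Tensor:
        return self.mlp_fc2(relu(self.mlp_fc1(v)))

    def hybrid_channel_attention(self, f_img: Tensor, e_cli: Tensor) -> Tensor:
        """Gate channels with pooled image statistics plus the embedded
        clinical vector."""
        if f_img.shape[1] != self.c_img or e_cli.shape[-1] != self.c_img:
            raise ValueError("channel dimension mismatch in hybrid channel attention")
        b, c = f_img.shape[:2]
        f_avg = f_img.mean(axis=(2, 3, 4))  # GAP -> [B, C]
        f_max = f_img.max(axis=(2, 3, 4))  # GMP -> [B, C]
        m_hc = sigmoid(self._channel_mlp(f_avg) + self._channel_mlp(f_max) + e_cli)
        return f_img * m_hc.reshape(b, c, 1, 1, 1)

    def spatial_attention(self, f_hc: Tensor) -> Tensor:
        """Gate locations from channel-mean and channel-max maps."""
        avg = f_hc.mean(axis=1, keepdims=True)
        mx = f_hc.max(axis=1, keepdims=True)
        m_s = sigmoid(self.spatial_conv(concatenate([avg, mx], axis=1)))
        return f_hc * m_s

    # -- full module ---------------------------------------------------
    def forward(self, f_img: Tensor, f_cli: Tensor) -> Tensor:
        return self.spatial_attention(
            self.hybrid_channel_attention(f_img, self.embed_clinical(f_cli))
        )
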