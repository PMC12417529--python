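"""3-D residual convolutional image encoder.

Each imaging modality (structural MRI, FDG-PET) is encoded by its own
ResNet-style stack of basic residual blocks (two 3x3x3 convolutions
plus an identity or 1x1x1-projection shortcut).  The stem is a 7x7x7
stride-2 convolution followed by stride-2 max pooling, so the stem
alone downsamples by 4; later stages each optionally halve resolution.

Two presets are provided:

``full``
    widths (32, 64, 128, 256), 2 blocks per stage, stage strides
    (1, 2, 2, 2): total downsampling x32, mapping a 96 x 128 x 96
    volume to a [256, 3, 4, 3] feature map.
``test``
    widths (8, 16, 32, 64), 1 block per stage, stage strides
    (1, 2, 1, 1): total downsampling x8, mapping 24 x 32 x 24 to
    [64, 3, 4, 3] — the same 36-token layout at a CPU-friendly scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, relu
from .nn import BatchNorm3d, Conv3d, MaxPool3d, Module, ModuleList

__all__ = ["EncoderConfig", "ResNet3d", "BasicBlock3d"]


@dataclass(frozen=True)
class EncoderConfig:
    stage_widths: tuple[int, int, int, int] = (32, 64, 128, 256)
    blocks_per_stage: tuple[int, int, int, int] = (2, 2, 2, 2)
    stage_strides: tuple[int, int, int, int] = (1, 2, 2, 2)
    stem_kernel: int = 7
    stem_stride: int = 2
    preset: str = "full"

    def __post_init__(self):
        if len(self.stage_widths) != 4 or len(self.blocks_per_stage) != 4:
            raise ValueError("encoder config requires 4 stages")
        if any(b < 1 for b in self.blocks_per_stage):
            raise ValueError("blocks_per_stage must be >= 1")
        if not all(a < b for a, b in zip(self.stage_widths, self.stage_widths[1:])):
            raise ValueError("stage widths must be strictly increasing")

    @classmethod
    def from_preset(cls, name: str) -> "EncoderConfig":
        if name == "full":
            return cls(preset="full")
        if name == "test":
            return cls(
                stage_widths=(8, 16, 32, 64),
                blocks_per_stage=(1, 1, 1, 1),
                stage_strides=(1, 2, 1, 1),
                preset="test",
            )
        raise ValueError(f"unknown encoder preset {name!r}")

    @property
    def out_channels(self) -> int:
        return self.stage_widths[-1]

    @property
    def total_downsample(self) -> int:
        return self.stem_stride * 2 * int(np.prod(self.stage_strides))

    def output_spatial(self, input_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        """Stride arithmetic for the feature-map spatial dims."""

        def down(n: int, k: int, s: int, p: int) -> int:
            return (n + 2 * p - k) // s + 1

        if min(input_shape) < self.total_downsample:
            raise ValueError(
                f"input {input_shape} smaller than the total downsampling "
                f"factor x{self.total_downsample}"
            )
        dims = list(input_shape)
        for i in range(3):
            n = down(dims[i], self.stem_kernel, self.stem_stride, self.stem_kernel // 2)
            n = down(n, 3, 2, 1)  # stem max-pool
            for s in self.stage_strides:
                n = down(n, 3, s, 1)
            dims[i] = n
        if min(dims) < 1:
            raise ValueError(
                f"input {input_shape} too small for total downsampling "
                f"x{self.total_downsample}"
            )
        return tuple(dims)


class BasicBlock3d(Module):
    """Two 3x3x3 convs with batch norm and an identity/projection shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng):
        super().__init__()
        self.conv1 = Conv3d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm3d(out_ch)
        self.conv2 = Conv3d(out_ch, out_ch, 3, stride=1, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm3d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.shortcut_conv = Conv3d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.shortcut_bn = BatchNorm3d(out_ch)
        else:
            self.shortcut_conv = None
            self.shortcut_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        if self.shortcut_conv is not None:
            x = self.shortcut_bn(self.shortcut_conv(x))
        return relu(out + x)


class ResNet3d(Module):
    """Residual encoder mapping [B, 1, D, H, W] to [B, C_img, d, h, w]."""

    def __init__(self, config: EncoderConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        w = config.stage_widths
        self.stem = Conv3d(
            1,
            w[0],
            config.stem_kernel,
            stride=config.stem_stride,
            padding=config.stem_kernel // 2,
            bias=False,
            rng=rng,
        )
        self.stem_bn = BatchNorm3d(w[0])
        self.pool = MaxPool3d(3, 2, 1)
        stages = []
        in_ch = w[0]
        for width, n_blocks, stride in zip(w, config.blocks_per_stage, config.stage_strides):
            blocks = []
            for b in range(n_blocks):
                blocks.append(BasicBlock3d(in_ch, width, stride if b == 0 else 1, rng))
                in_ch = width
            stages.append(ModuleList(blocks))
        self.stages = ModuleList(stages)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 5:
            raise ValueError("expected [B, 1, D, H, W] input batch")
        out = self.pool(relu(self.stem_bn(self.stem(x))))
        for stage in self.stages:
            for block in stage:
                out = block(out)
        return out
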