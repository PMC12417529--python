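"""Neural-network building blocks and the Adam optimizer.

Modules hold :class:`~trilightnet.autodiff.Tensor` parameters and
sub-modules as plain attributes; :meth:`Module.named_parameters` walks
the attribute tree recursively, which gives every parameter a stable
dotted name used by the checkpoint format.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv3d, gelu, matmul, maxpool3d, relu, sqrt

__all__ = [
    "Module",
    "ModuleList",
    "Linear",
    "Conv3d",
    "BatchNorm3d",
    "LayerNorm",
    "MaxPool3d",
    "Adam",
]


class Module:
    """Base class: parameter/submodule registry plus train/eval mode."""

    def __init__(self):
        self.training = True

    # -- registry ------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        """Non-trainable state (e.g. batch-norm running statistics)."""
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield from value.named_buffers(prefix + name + ".")
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)

    def _submodules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value

    def apply(self, fn):
        fn(self)
        for m in self._submodules():
            m.apply(fn)
        return self

    # -- mode ----------------------------------------------------------
    def train(self, mode: bool = True):
        def setter(m):
            m.training = mode

        return self.apply(setter)

    def eval(self):
        return self.train(False)

    # -- state ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state["buffer:" + name] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        expected = set(params) | {"buffer:" + n for n, _ in self.named_buffers()}
        missing = expected - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]}")
        for name, p in params.items():
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].copy()
        self._load_buffers(state, "")

    def _load_buffers(self, state, prefix):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                value._load_buffers(state, prefix + name + ".")
        for name in getattr(self, "_buffers", ()):
            setattr(self, name, state["buffer:" + prefix + name].copy())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items = list(modules)
        for i, m in enumerate(self._items):
            setattr(self, str(i), m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


def _kaiming_uniform(rng, shape, fan_in, dtype):
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Linear(Module):
    """Affine map y = x W^T + b on the last axis."""

    def __init__(self, in_features, out_features, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(
            _kaiming_uniform(rng, (out_features, in_features), in_features, dtype),
            requires_grad=True,
        )
        if bias:
            bound = 1.0 / np.sqrt(in_features)
            self.bias = Tensor(
                rng.uniform(-bound, bound, size=out_features).astype(dtype),
                requires_grad=True,
            )
        else:
            self.bias = None

    def forward(self, x):
        out = matmul(x, self.weight.transpose())
        if self.bias is not None:
            out = out + self.bias
        return out

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias


class Conv3d(Module):
    def __init__(
        self,
        in_channels,
        out_channels,
        kernel_size,
        stride=1,
        padding=0,
        bias=True,
        rng=None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = (kernel_size,) * 3 if isinstance(kernel_size, int) else tuple(kernel_size)
        fan_in = in_channels * int(np.prod(k))
        self.stride = stride
        self.padding = padding
        self.weight = Tensor(
            (rng.standard_normal((out_channels, in_channels) + k) * np.sqrt(2.0 / fan_in)).astype(
                dtype
            ),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x):
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias


class BatchNorm3d(Module):
    """Batch normalization over (B, D, H, W) per channel.

    Training mode normalizes with batch statistics and updates running
    moments; evaluation mode uses the running moments, which makes the
    forward pass deterministic.
    """

    _buffers = ("running_mean", "running_var")

    def __init__(self, num_features, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(num_features, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)

    def forward(self, x):
        c = x.shape[1]
        shape = (1, c, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3, 4), keepdims=True)
            n = float(np.prod([x.shape[i] for i in (0, 2, 3, 4)]))
            unbiased = var.data.reshape(-1) * (n / max(n - 1.0, 1.0))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = xc / sqrt(var + self.eps)
        else:
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class LayerNorm(Module):
    """Layer normalization over the last axis."""

    def __init__(self, num_features, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.weight = Tensor(np.ones(num_features, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=dtype), requires_grad=True)

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return (xc / sqrt(var + self.eps)) * self.weight + self.bias


class MaxPool3d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return maxpool3d(x, self.kernel_size, self.stride, self.padding)


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of parameters."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


__all__ += ["relu", "gelu"]
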