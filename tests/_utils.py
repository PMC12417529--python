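"""Shared test helpers: finite-difference gradients and small oracles."""

import numpy as np

from trilightnet.autodiff import Tensor


def numeric_grad(fn, x, eps=1e-6):
    """Central finite-difference gradient of scalar-valued fn(ndarray)."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat_x = x.reshape(-1)
    flat_g = g.reshape(-1)
    for i in range(flat_x.size):
        xp = x.copy()
        xm = x.copy()
        xp.reshape(-1)[i] += eps
        xm.reshape(-1)[i] -= eps
        flat_g[i] = (fn(xp) - fn(xm)) / (2 * eps)
    return g


def analytic_grad(fn, x):
    """Gradient of scalar Tensor-valued fn at x via backprop."""
    t = Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)
    out = fn(t)
    out.backward()
    return t.grad


def check_grad(fn_tensor, fn_plain, x, atol=1e-6):
    ana = analytic_grad(fn_tensor, x)
    num = numeric_grad(fn_plain, x)
    assert np.abs(ana - num).max() < atol, np.abs(ana - num).max()


def cast_model_f64(module):
    """Promote all parameters and buffers of a module tree to float64
    (for oracle comparisons at 1e-12 tolerances)."""
    for _, p in module.named_parameters():
        p.data = p.data.astype(np.float64)
    for obj in _walk_modules(module):
        for name in getattr(obj, "_buffers", ()):
            setattr(obj, name, getattr(obj, name).astype(np.float64))
    return module


def _walk_modules(module):
    yield module
    for sub in module._submodules():
        yield from _walk_modules(sub)
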