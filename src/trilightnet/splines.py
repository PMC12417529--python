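"""Uniform B-spline bases for KAN edge functions.

A :class:`SplineGrid` covers a fixed input range [lo, hi] with ``G``
uniform intervals; the knot vector is extended by ``k`` extra uniform
knots on each side so that exactly ``G + k`` degree-``k`` basis
functions are supported, and the basis forms a partition of unity on
[lo, hi].  Inputs outside the range are evaluated on the polynomial
extension of the boundary pieces (the order-0 interval selection is
clamped to the real grid while the recursion weights use the actual
input), so the map stays smooth and differentiable everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, _node

__all__ = ["SplineGrid", "bspline_basis", "bspline_basis_tensor"]


@dataclass(frozen=True)
class SplineGrid:
    """Knot layout for a uniform B-spline basis of order (degree) ``k``."""

    order: int = 3
    grid_size: int = 5
    lo: float = -2.0
    hi: float = 2.0
    knots: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.hi <= self.lo:
            raise ValueError("SplineGrid requires hi > lo")
        if self.grid_size < 1 or self.order < 0:
            raise ValueError("SplineGrid requires grid_size >= 1 and order >= 0")
        h = (self.hi - self.lo) / self.grid_size
        n_knots = self.grid_size + 2 * self.order + 1
        knots = self.lo - self.order * h + h * np.arange(n_knots)
        if np.any(np.diff(knots) <= 0):
            raise ValueError("degenerate knot vector")
        object.__setattr__(self, "knots", knots)

    @property
    def n_basis(self) -> int:
        return self.grid_size + self.order

    @property
    def spacing(self) -> float:
        return (self.hi - self.lo) / self.grid_size


def _basis_orders(x: np.ndarray, grid: SplineGrid):
    """All Cox-de Boor orders up to ``grid.order``.

    Returns the degree-k basis values ``B`` with shape x.shape + (G+k,)
    and the degree-(k-1) values used for the derivative (or None for
    k = 0).
    """
    t = grid.knots
    k = grid.order
    G = grid.grid_size
    h = grid.spacing
    x = np.asarray(x, dtype=np.float64)
    # order-0: indicator of the interval containing x, clamped to the
    # real grid so out-of-range inputs extend the boundary polynomial
    idx = np.clip(np.floor((x - grid.lo) / h).astype(int), 0, G - 1) + k
    n_int = len(t) - 1
    B = np.zeros(x.shape + (n_int,))
    np.put_along_axis(B, idx[..., None], 1.0, axis=-1)
    prev = None
    for r in range(1, k + 1):
        n_b = n_int - r
        left_t = t[:n_b]
        right_t = t[r + 1 : r + 1 + n_b]
        xe = x[..., None]
        new = (xe - left_t) / (t[r : r + n_b] - left_t) * B[..., :n_b] + (
            right_t - xe
        ) / (right_t - t[1 : 1 + n_b]) * B[..., 1 : 1 + n_b]
        prev = B
        B = new
    return B, (prev if k > 0 else None)


def bspline_basis(x, grid: SplineGrid) -> np.ndarray:
    """Evaluate the ``G + k`` basis functions at ``x`` (any array shape)."""
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("bspline_basis: non-finite input")
    B, _ = _basis_orders(x, grid)
    return B


def bspline_basis_deriv(x, grid: SplineGrid) -> np.ndarray:
    """d/dx of each basis function (uniform-knot derivative formula)."""
    k = grid.order
    if k == 0:
        return np.zeros(np.shape(x) + (grid.n_basis,))
    _, Bkm1 = _basis_orders(x, grid)
    h = grid.spacing
    n_b = grid.n_basis
    return (Bkm1[..., :n_b] - Bkm1[..., 1 : 1 + n_b]) / h


def bspline_basis_tensor(x: Tensor, grid: SplineGrid) -> Tensor:
    """Differentiable basis evaluation: x [...,] -> [..., G+k]."""
    B = bspline_basis(x.data, grid).astype(x.data.dtype)

    def backward(g):
        dB = bspline_basis_deriv(x.data, grid)
        return ((g * dB).sum(axis=-1).astype(x.data.dtype),)

    return _node(B, (x,), backward)
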