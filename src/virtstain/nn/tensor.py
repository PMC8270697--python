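"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the micrograd lineage, extended to tensors
and to higher-order derivatives: every vector-Jacobian product is itself
written in terms of the engine's primitives, so ``grad(..., create_graph=True)``
returns differentiable tensors. This is what the adversarial penalties
(gradient penalty, R1) require — the critic loss contains the norm of an
input gradient, and training differentiates *through* that norm.

Only the primitives the package's networks need are implemented; convolution
is expressed as ``im2col`` + ``matmul`` so that its input/weight gradients
(and their gradients) come out of the same machinery.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "grad", "backward", "no_grad", "as_tensor"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjp: Callable[[Tensor], Sequence[Tensor | None]] | None = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction --------------------------------------------
    @staticmethod
    def _make(data, parents, vjp) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.detach_if_const(), self.shape),
                _unbroadcast(g * self.detach_if_const(), other.shape),
            ),
        )

    __rmul__ = __mul__

    def detach_if_const(self):
        # keep graph links so second-order terms flow; this is the tensor itself
        return self

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor._make(
            self.data ** e,
            (self,),
            lambda g: (g * (self ** (e - 1.0)) * e,),
        )

    def __matmul__(self, other):
        other = as_tensor(other)

        def vjp(g: Tensor):
            ga = g @ other.swap_last()
            gb = self.swap_last() @ g
            return _unbroadcast_matmul(ga, self.shape), _unbroadcast_matmul(gb, other.shape)

        return Tensor._make(self.data @ other.data, (self, other), vjp)

    def swap_last(self) -> "Tensor":
        axes = list(range(self.ndim))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return self.transpose(axes)

    # -- elementwise functions ------------------------------------------
    def exp(self):
        return Tensor._make(np.exp(self.data), (self,), lambda g: (g * self.exp(),))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self,))

    def sqrt(self):
        return self ** 0.5

    def abs(self):
        sign = Tensor(np.sign(self.data))
        return Tensor._make(np.abs(self.data), (self,), lambda g: (g * sign,))

    def tanh(self):
        return Tensor._make(np.tanh(self.data), (self,), lambda g: (g * (1.0 - self.tanh() ** 2.0),))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(s, (self,), lambda g: (g * self.sigmoid() * (1.0 - self.sigmoid()),))

    def softplus(self):
        # log(1 + e^x), overflow-safe
        out = np.logaddexp(0.0, self.data)
        return Tensor._make(out, (self,), lambda g: (g * self.sigmoid(),))

    def leaky_relu(self, slope: float = 0.2):
        mask = Tensor(np.where(self.data > 0, 1.0, slope))
        return Tensor._make(self.data * mask.data, (self,), lambda g: (g * mask,))

    def relu(self):
        return self.leaky_relu(0.0)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        ax = _norm_axes(axis, self.ndim)

        def vjp(g: Tensor):
            gd = g
            if not keepdims and ax is not None:
                shape = list(self.shape)
                for a in ax:
                    shape[a] = 1
                gd = gd.reshape(tuple(shape))
            return (gd.broadcast_to(self.shape),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        ax = _norm_axes(axis, self.ndim)
        n = self.size if ax is None else int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        onehot = np.zeros(self.shape)
        np.put_along_axis(onehot, np.expand_dims(idx, axis), 1.0, axis=axis)
        mask = Tensor(onehot)

        def vjp(g: Tensor):
            gd = g if keepdims else g.expand_dims(axis)
            return (gd.broadcast_to(self.shape) * mask,)

        return Tensor._make(self.data.max(axis=axis, keepdims=keepdims), (self,), vjp)

    # -- shape ops -------------------------------------------------------
    def reshape(self, shape):
        shape = tuple(shape)
        return Tensor._make(self.data.reshape(shape), (self,), lambda g: (g.reshape(self.shape),))

    def expand_dims(self, axis: int):
        shape = list(self.shape)
        shape.insert(axis if axis >= 0 else axis + self.ndim + 1, 1)
        return self.reshape(shape)

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        return Tensor._make(self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),))

    def broadcast_to(self, shape):
        shape = tuple(shape)
        if self.shape == shape:
            return self
        return Tensor._make(
            np.broadcast_to(self.data, shape).copy(),
            (self,),
            lambda g: (_unbroadcast(g, self.shape),),
        )

    def __getitem__(self, key):
        return Tensor._make(
            self.data[key].copy(),
            (self,),
            lambda g: (g.scatter(key, self.shape),),
        )

    def scatter(self, key, shape) -> "Tensor":
        """Place this tensor at ``key`` inside zeros of ``shape`` (adjoint of slicing)."""
        out = np.zeros(shape)
        out[key] = self.data
        return Tensor._make(out, (self,), lambda g: (g[key],))

    # -- conv building blocks -------------------------------------------
    def im2col(self, kernel: int, stride: int, padding: int):
        """(N, C, H, W) -> (N, C*k*k, oH*oW) patch matrix."""
        N, C, H, W = self.shape
        oH = (H + 2 * padding - kernel) // stride + 1
        oW = (W + 2 * padding - kernel) // stride + 1

        def vjp(g: Tensor):
            return (g.col2im((N, C, H, W), kernel, stride, padding),)

        return Tensor._make(
            _im2col_np(self.data, kernel, stride, padding), (self,), vjp
        )

    def col2im(self, img_shape, kernel: int, stride: int, padding: int):
        """Adjoint of :meth:`im2col`: scatter-add patches back to an image."""

        def vjp(g: Tensor):
            return (g.im2col(kernel, stride, padding),)

        return Tensor._make(
            _col2im_np(self.data, img_shape, kernel, stride, padding), (self,), vjp
        )

    def upsample2x(self):
        """Nearest-neighbour 2x spatial upsampling of (N, C, H, W)."""
        N, C, H, W = self.shape

        def vjp(g: Tensor):
            return (g.reshape((N, C, H, 2, W, 2)).sum(axis=(3, 5)),)

        up = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)
        return Tensor._make(up, (self,), vjp)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g: Tensor):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            key = tuple(
                slice(lo, hi) if a == axis % g.ndim else slice(None) for a in range(g.ndim)
            )
            grads.append(g[key])
        return grads

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


# -- backward machinery ----------------------------------------------------


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(
    output: Tensor,
    inputs: Iterable[Tensor],
    create_graph: bool = False,
    grad_output: Tensor | None = None,
) -> list[Tensor]:
    """Gradients of a scalar ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own tape and
    can be differentiated again (needed for gradient-penalty terms).
    """
    inputs = list(inputs)
    input_ids = {id(t) for t in inputs}
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads: dict[int, Tensor] = {id(output): grad_output}

    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = bool(create_graph)
    try:
        for node in reversed(_toposort(output)):
            if id(node) in input_ids:
                g = grads.get(id(node))
            else:
                g = grads.pop(id(node), None)
            if g is None or node._vjp is None:
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                acc = grads.get(id(p))
                grads[id(p)] = pg if acc is None else acc + pg
            # free memory for intermediate grads as we go
    finally:
        _GRAD_ENABLED = prev

    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out


def backward(loss: Tensor, params: Iterable[Tensor]) -> None:
    """Accumulate ``.grad`` (numpy) on ``params`` from a scalar loss."""
    params = list(params)
    gs = grad(loss, params, create_graph=False)
    for p, g in zip(params, gs):
        if p.grad is None:
            p.grad = g.data.copy()
        else:
            p.grad += g.data


# -- numpy kernels ---------------------------------------------------------


def _im2col_np(x: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    N, C, H, W = x.shape
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    oH = (H + 2 * p - k) // s + 1
    oW = (W + 2 * p - k) // s + 1
    cols = np.empty((N, C, k, k, oH, oW), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + s * oH : s, j : j + s * oW : s]
    return cols.reshape(N, C * k * k, oH * oW)


def _col2im_np(cols: np.ndarray, img_shape, k: int, s: int, p: int) -> np.ndarray:
    N, C, H, W = img_shape
    oH = (H + 2 * p - k) // s + 1
    oW = (W + 2 * p - k) // s + 1
    cols = cols.reshape(N, C, k, k, oH, oW)
    out = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + s * oH : s, j : j + s * oW : s] += cols[:, :, i, j]
    if p:
        out = out[:, :, p:-p, p:-p]
    return out


def _norm_axes(axis, ndim):
    if axis is None:
        return None
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


def _unbroadcast(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Reduce a gradient back to the shape of a broadcast operand."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, ss) in enumerate(zip(g.shape, shape)) if ss == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g if g.shape == shape else g.reshape(shape)


def _unbroadcast_matmul(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(
        i for i in range(g.ndim - 2) if shape[i] == 1 and g.shape[i] != 1
    )
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g
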