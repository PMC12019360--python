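"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine records a dynamic computation graph when gradients are enabled and
any operand requires them. ``Tensor.backward()`` runs a topological sweep and
accumulates gradients as plain float64 ndarrays. Convolution and transposed
convolution are implemented as single primitives (im2col / col2im) so the
heavy lifting stays inside BLAS matmuls.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        # backward closures never mutate gradient arrays in place, so storing a
        # view here is safe; accumulation always allocates a fresh array
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic info --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)
        out_data = a.data ** e

        def bwd(g):
            a._accum(g * e * a.data ** (e - 1.0))

        return Tensor._make(out_data, (a,), bwd)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bwd(g):
            a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bwd)

    # -- reductions & reshapes ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).astype(np.float64))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).astype(np.float64))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = 1
            for ax in axes:
                n *= self.data.shape[ax]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bwd(g):
            a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)

    # -- linear algebra ------------------------------------------------------
    def matmul(self, other: "Tensor"):
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bwd)

    def __matmul__(self, other):
        return self.matmul(other)

    # -- activations ---------------------------------------------------------
    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = np.where(a.data > 0, 1.0, slope)

        def bwd(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bwd)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bwd)


# -- convolution primitives ---------------------------------------------------

def _im2col(xp: np.ndarray, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    """(B, C, Hp, Wp) -> (B, C*k*k, ho*wo) patch matrix."""
    b, c = xp.shape[:2]
    cols = np.empty((b, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
    return cols.reshape(b, c * k * k, ho * wo)


def _col2im(cols: np.ndarray, xp_shape: tuple, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    b, c = xp_shape[:2]
    xp = np.zeros(xp_shape, dtype=cols.dtype)
    cols = cols.reshape(b, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + s * ho:s, j:j + s * wo:s] += cols[:, :, i, j]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int, padding: int) -> Tensor:
    """2-D convolution; weight (F, C, k, k), x (B, C, H, W)."""
    b, c, h, w = x.data.shape
    f, _, k, _ = weight.data.shape
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    if ho <= 0 or wo <= 0:
        raise ValueError(
            f"conv2d: kernel {k} stride {stride} does not fit input side {h}"
        )
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    cols = _im2col(xp, k, stride, ho, wo)                      # (B, CKK, L)
    wmat = weight.data.reshape(f, -1)                          # (F, CKK)
    out = np.matmul(wmat, cols) + bias.data.reshape(1, f, 1)   # (B, F, L)
    out = out.reshape(b, f, ho, wo)

    def bwd(g):
        gmat = g.reshape(b, f, ho * wo)
        if weight.requires_grad:
            gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(gw.reshape(weight.data.shape))
        if bias.requires_grad:
            bias._accum(gmat.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gmat)                    # (B, CKK, L)
            gxp = _col2im(gcols, xp.shape, k, stride, ho, wo)
            if padding:
                gxp = gxp[:, :, padding:padding + h, padding:padding + w]
            x._accum(gxp)

    return Tensor._make(out, (x, weight, bias), bwd)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int, padding: int) -> Tensor:
    """2-D transposed convolution; weight (C_in, C_out, k, k), x (B, C_in, H, W)."""
    b, cin, h, w = x.data.shape
    _, cout, k, _ = weight.data.shape
    ho = (h - 1) * stride - 2 * padding + k
    wo = (w - 1) * stride - 2 * padding + k
    if ho <= 0 or wo <= 0:
        raise ValueError("conv_transpose2d: output size would be non-positive")
    xmat = x.data.reshape(b, cin, h * w)
    wmat = weight.data.reshape(cin, cout * k * k)
    cols = np.matmul(wmat.T, xmat)                             # (B, C_out*k*k, L)
    padded_shape = (b, cout, ho + 2 * padding, wo + 2 * padding)
    outp = _col2im(cols, padded_shape, k, stride, h, w)
    out = outp[:, :, padding:padding + ho, padding:padding + wo]
    out = out + bias.data.reshape(1, cout, 1, 1)

    def bwd(g):
        if padding:
            gp = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        else:
            gp = g
        gcols = _im2col(gp, k, stride, h, w)                   # (B, C_out*k*k, L)
        if weight.requires_grad:
            gw = np.matmul(xmat, gcols.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(gw.reshape(weight.data.shape))
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.matmul(wmat, gcols)                        # (B, C_in, L)
            x._accum(gx.reshape(b, cin, h, w))

    return Tensor._make(out, (x, weight, bias), bwd)
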