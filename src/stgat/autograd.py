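"""Minimal reverse-mode automatic differentiation on numpy arrays.

The models in this package (convolutional blocks, the dual-coefficient
graph-attention layer, fully connected heads) are small enough to train on a
single CPU, so they are built on this compact tape-based engine rather than a
heavyweight framework.  Every operation records its parents and a closure
that maps the output gradient to parent gradients; :meth:`Tensor.backward`
walks the tape in reverse topological order.

Gradients of every primitive are checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph construction --------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        needs = any(p.requires_grad or p._parents for p in parents)
        if needs:
            return Tensor(data, requires_grad=False, _parents=parents, _backward=backward)
        return Tensor(data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, like=self)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other, like=self))

    def __rsub__(self, other):
        return as_tensor(other, like=self) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, like=self)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, like=self)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other, like=self)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    @property
    def T(self):
        return self.transpose()

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * np.expm1(self.data))

        def backward(g):
            return (g * np.where(pos, 1.0, out_data + alpha),)

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- spatial ops for (N, C, H, W) activations ------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor", padding: int = 1):
        """3x3-style stride-1 convolution via im2col.

        self: (N, C, H, W); weight: (O, C, kh, kw); bias: (O,).
        """
        x = self.data
        n, c, h, w = x.shape
        o, c2, kh, kw = weight.data.shape
        if c != c2:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        ho, wo = h + 2 * padding - kh + 1, w + 2 * padding - kw + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        # win: (N, C, Ho, Wo, kh, kw) -> cols: (N*Ho*Wo, C*kh*kw)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * kh * kw
        )
        wmat = weight.data.reshape(o, -1)
        out = cols @ wmat.T + bias.data
        out_data = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

        def backward(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
            gw = (g2.T @ cols).reshape(weight.data.shape)
            gb = g2.sum(axis=0)
            gcols = (g2 @ wmat).reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + ho, j : j + wo] += gcols[:, :, :, :, i, j]
            gx = gxp[:, :, padding : padding + h, padding : padding + w]
            return (gx, gw, gb)

        return Tensor._make(out_data, (self, weight, bias), backward)

    def maxpool2d(self, k: int):
        """Non-overlapping k x k max pooling; H and W must be divisible by k."""
        x = self.data
        n, c, h, w = x.shape
        if h % k or w % k:
            raise ValueError(f"maxpool2d: spatial size {h}x{w} not divisible by {k}")
        ho, wo = h // k, w // k
        xr = x.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho, wo, k * k
        )
        idx = xr.argmax(axis=-1)
        out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gr = np.zeros((n, c, ho, wo, k * k), dtype=g.dtype)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gx = gr.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(
                n, c, h, w
            )
            return (gx,)

        return Tensor._make(out_data, (self,), backward)

    # -- backprop ------------------------------------------------------------
    def backward(self, grad=None):
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not (parent.requires_grad or parent._parents):
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=False)
                else:
                    parent.grad = parent.grad + g.astype(parent.data.dtype, copy=False)


def as_tensor(value, like: Tensor | None = None) -> Tensor:
    if isinstance(value, Tensor):
        return value
    dtype = like.data.dtype if like is not None else None
    return Tensor(np.asarray(value, dtype=dtype))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`, splitting the gradient on the way back."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        slicer = [slice(None)] * g.ndim
        grads = []
        for i in range(len(sizes)):
            slicer[axis] = slice(offsets[i], offsets[i + 1])
            grads.append(g[tuple(slicer)])
        return tuple(grads)

    needs = any(t.requires_grad or t._parents for t in tensors)
    if needs:
        return Tensor(out_data, _parents=tuple(tensors), _backward=backward)
    return Tensor(out_data)
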