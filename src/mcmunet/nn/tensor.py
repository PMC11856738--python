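"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The segmentation network in this package needs only a small, fixed set of
differentiable operations (dense/convolutional linear maps, instance
normalisation, leaky rectifier, softmax, concatenation and reductions).
They are implemented here as a define-by-run tape: each operation records
its parents and a closure that routes the output gradient back to them.
``Tensor.backward`` topologically sorts the tape and accumulates gradients.

Arrays keep whatever dtype they are given; the network uses float32 for
speed, gradient-check tests use float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- elementwise arithmetic ----------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._node(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._node(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._node(np.log(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclipped entries."""
        mask = (self.data > lo) & (self.data < hi)
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            self._accum(g * mask)

        return Tensor._node(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        pos = self.data > 0
        out_data = np.where(pos, self.data, slope * self.data)

        def backward(g):
            self._accum(np.where(pos, g, slope * g))

        return Tensor._node(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % len(shape) for a in axes)
                gg = np.expand_dims(gg, axes)
            self._accum(np.broadcast_to(gg, shape).copy())

        return Tensor._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.data.shape

        def backward(g):
            self._accum(g.reshape(in_shape))

        return Tensor._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._node(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    # -- linear algebra -------------------------------------------------------

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape)
                )
            if other.requires_grad:
                other._accum(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape)
                )

        return Tensor._node(out_data, (self, other), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            self._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

        return Tensor._node(y, (self,), backward)

    # -- backward pass --------------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._node(out_data, tensors, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation: x (N,C,H,W), w (Cout,Cin,kh,kw)."""
    n, cin, _, _ = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin_w}")
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    ho, wo = win.shape[2], win.shape[3]
    # materialise im2col once; the same buffer serves forward and dW
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    col = col.reshape(n * ho * wo, cin * kh * kw)
    wmat = w.data.reshape(cout, -1)
    out = (col @ wmat.T).reshape(n, ho, wo, cout)
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        out += b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gt = None
        if w.requires_grad or x.requires_grad:
            # (N, Ho, Wo, Co) contiguous: one transpose shared by both grads
            gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        if w.requires_grad:
            w._accum((gt.T @ col).reshape(w.data.shape).astype(w.data.dtype, copy=False))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # dcol = g @ W as one GEMM, then fold taps back onto the grid
            dcol = (gt @ wmat).reshape(n, ho, wo, cin, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                        dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._node(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, stride: int = 2) -> Tensor:
    """Transposed convolution with kernel size == stride (block upsampling).

    x: (N,Cin,H,W), w: (Cin,Cout,k,k); output (N,Cout,H*k,W*k).
    """
    n, cin, h, ww_ = x.data.shape
    cin_w, cout, k, k2 = w.data.shape
    if cin != cin_w or k != stride or k != k2:
        raise ValueError("conv_transpose2d expects square kernel == stride")
    out6 = np.einsum("ncij,cokl->noikjl", x.data, w.data, optimize=True)
    out = out6.reshape(n, cout, h * k, ww_ * k)

    def backward(g):
        g6 = g.reshape(n, cout, h, k, ww_, k)
        if x.requires_grad:
            x._accum(np.einsum("noikjl,cokl->ncij", g6, w.data, optimize=True))
        if w.requires_grad:
            w._accum(np.einsum("ncij,noikjl->cokl", x.data, g6, optimize=True))

    return Tensor._node(out, (x, w), backward)


def instance_norm2d(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise each (sample, channel) plane to zero mean / unit variance."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv

    def backward(g):
        gm = g.mean(axis=(2, 3), keepdims=True)
        gx = (g * xhat).mean(axis=(2, 3), keepdims=True)
        x._accum(inv * (g - gm - xhat * gx))

    return Tensor._node(xhat, (x,), backward)
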