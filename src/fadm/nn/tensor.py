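"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 numpy array and records the operations
applied to it; :meth:`Tensor.backward` walks the recorded graph in reverse
topological order and accumulates gradients.  The op set is exactly what
the frequency-aware U-Net needs: broadcast-aware arithmetic, reductions,
reshapes, (batched) matmul, 2D convolution via im2col, softmax, SiLU,
nearest-neighbour upsampling and the packed orthonormal Haar transform
(whose adjoint is its inverse, since the transform is an isometry).

Everything runs in float64 so that training is bit-reproducible across
runs on the same machine and finite-difference gradient checks are sharp.
"""

from __future__ import annotations

import numpy as np

from ..wavelet import dwt2, idwt2, pack_subbands, unpack_subbands

__all__ = ["Tensor", "concat", "matmul", "conv2d", "softmax", "silu",
           "upsample_nearest2", "haar_packed", "ihaar_packed"]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.array(g)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- shape views ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g, self=self, old=old):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g, self=self, inv=inv):
            self._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), bw)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        if not isinstance(other, Tensor):
            other = Tensor(other)
        a, b = self, other

        def bw(g, a=a, b=b):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g, self=self):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-other if isinstance(other, Tensor) else Tensor(-_as_array(other)))

    def __rsub__(self, other) -> "Tensor":
        return (-self) + other

    def __mul__(self, other) -> "Tensor":
        if not isinstance(other, Tensor):
            other = Tensor(other)
        a, b = self, other

        def bw(g, a=a, b=b):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def pow_const(self, c: float) -> "Tensor":
        x = self.data

        def bw(g, self=self, x=x, c=c):
            self._accum(g * c * np.power(x, c - 1.0))

        return Tensor._make(np.power(x, c), (self,), bw)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.data.shape

        def bw(g, self=self, shape=shape, axis=axis, keepdims=keepdims):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# -- free functions --------------------------------------------------------


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g, tensors=tensors, offsets=offsets, axis=axis):
        sl = [slice(None)] * g.ndim
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; batched if inputs share identical leading dims."""

    def bw(g, a=a, b=b):
        if a.requires_grad:
            a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    return Tensor._make(a.data @ b.data, (a, b), bw)


def silu(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    y = x.data * s

    def bw(g, x=x, s=s, y=y):
        x._accum(g * (s + y * (1.0 - s)))

    return Tensor._make(y, (x,), bw)


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)

    def bw(g, x=x, y=y):
        x._accum(y * (g - (g * y).sum(axis=-1, keepdims=True)))

    return Tensor._make(y, (x,), bw)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    col = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            col[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return col.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(col: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    col = col.reshape(n, c, kh, kw, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=col.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += col[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2D convolution (cross-correlation) on (N, C, H, W) input."""
    co, ci, kh, kw = weight.data.shape
    n = x.data.shape[0]
    col, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(co, ci * kh * kw)
    out = np.matmul(wmat, col)  # (co,k) @ (n,k,p) -> (n,co,p)
    if bias is not None:
        out += bias.data.reshape(1, co, 1)
    out = out.reshape(n, co, ho, wo)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g, x=x, weight=weight, bias=bias, col=col, wmat=wmat,
           co=co, ci=ci, kh=kh, kw=kw, stride=stride, padding=padding):
        gm = np.ascontiguousarray(g.reshape(g.shape[0], co, -1))
        if bias is not None and bias.requires_grad:
            bias._accum(gm.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.matmul(gm, col.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(gw.reshape(co, ci, kh, kw))
        if x.requires_grad:
            gcol = np.matmul(wmat.T, gm)
            x._accum(_col2im(gcol, x.data.shape, kh, kw, stride, padding))

    return Tensor._make(out, parents, bw)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling on (N, C, H, W)."""
    y = np.repeat(np.repeat(x.data, 2, axis=-2), 2, axis=-1)

    def bw(g, x=x):
        n, c, h2, w2 = g.shape
        x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(y, (x,), bw)


def haar_packed(x: Tensor) -> Tensor:
    """Orthonormal Haar DWT with (ll, lh, hl, hh) channel packing.

    (N, C, H, W) -> (N, 4C, H/2, W/2).  The transform is an isometry, so
    the adjoint needed for backprop is exactly the inverse transform.
    """
    y = pack_subbands(dwt2(x.data))

    def bw(g, x=x):
        x._accum(idwt2(unpack_subbands(g)))

    return Tensor._make(y, (x,), bw)


def ihaar_packed(x: Tensor) -> Tensor:
    """Inverse of :func:`haar_packed`: (N, 4C, H, W) -> (N, C, 2H, 2W)."""
    y = idwt2(unpack_subbands(x.data))

    def bw(g, x=x):
        x._accum(pack_subbands(dwt2(g)))

    return Tensor._make(y, (x,), bw)
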