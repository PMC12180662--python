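"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the package's trainable components need:
dense/broadcast arithmetic, matmul, ReLU/tanh/exp/log/sqrt, reductions,
reshape/concat/slicing, 2D convolution and transposed convolution (im2col),
plus ``detach`` for stop-gradient semantics. Gradients are accumulated by a
topological backward sweep from a scalar loss.

Every primitive is checked against central finite differences in the test
suite; the engine is deliberately small rather than general.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "permute_cols", "conv2d", "conv_transpose2d", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):  # dtype-preserving for floats
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward
        self._grad_borrowed = False

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, _parents=tuple(parents), _backward=backward)

    def _accum(self, g: np.ndarray):
        if not self.requires_grad:
            return
        if self.grad is None:
            if isinstance(g, np.ndarray) and g.shape == self.data.shape:
                # borrow without copying; copy lazily if accumulated into again
                self.grad = g
                self._grad_borrowed = True
            else:
                self.grad = np.array(np.broadcast_to(g, self.data.shape))
                self._grad_borrowed = False
        else:
            if self._grad_borrowed:
                self.grad = self.grad.copy()
                self._grad_borrowed = False
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar fast path, dtype-preserving
            def bw(g):
                self._accum(g)

            return Tensor._make(self.data + other, (self,), bw)
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def bw(g):
                self._accum(g * other)

            return Tensor._make(self.data * other, (self,), bw)
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), bw)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bw)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bw)

    # -- reductions / shape ops -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape

        def bw(g):
            self._accum(g.reshape(src_shape))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def __getitem__(self, idx):
        fancy = any(isinstance(i, (np.ndarray, list)) for i in (idx if isinstance(idx, tuple) else (idx,)))

        def bw(g):
            full = np.zeros_like(self.data)
            if fancy:
                np.add.at(full, idx, g)  # repeated indices accumulate
            else:
                full[idx] = g
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), bw)


def permute_cols(t: Tensor, perm: np.ndarray, inv: np.ndarray) -> Tensor:
    """Column permutation with O(1)-overhead backward (gather by the inverse)."""

    def bw(g):
        t._accum(g[:, inv])

    return Tensor._make(t.data[:, perm], (t,), bw)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


# -- 2D convolution ------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C, kh, kw, Ho, Wo) view via sliding windows."""
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # win: (N, C, Ho_full, Wo_full, kh, kw) -> stride subsample, reorder
    win = win[:, :, ::stride, ::stride, :, :]
    return np.transpose(win, (0, 1, 4, 5, 2, 3))


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`."""
    n, c, h, w = x_shape
    _, _, _, _, ho, wo = cols.shape
    x = np.zeros((n, c, h, w), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, i, j, :, :
            ]
    return x


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2D convolution, x (N,C,H,W), weight (O,C,kh,kw), bias (O,)."""
    x = Tensor._lift(x)
    weight = Tensor._lift(weight)
    o, c, kh, kw = weight.data.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    n, _, hp, wp = xd.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = _im2col(xd, kh, kw, stride)  # (N,C,kh,kw,Ho,Wo)
    cols2 = cols.reshape(n, c * kh * kw, ho * wo)
    w2 = weight.data.reshape(o, c * kh * kw)
    out = np.einsum("ok,nkl->nol", w2, cols2).reshape(n, o, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        g2 = g.reshape(n, o, ho * wo)
        if bias is not None:
            bias._accum(g.sum(axis=(0, 2, 3)))
        weight._accum(np.einsum("nol,nkl->ok", g2, cols2).reshape(weight.data.shape))
        if x.requires_grad:
            dcols = np.einsum("ok,nol->nkl", w2, g2).reshape(n, c, kh, kw, ho, wo)
            dx = _col2im(dcols, xd.shape, kh, kw, stride)
            if padding:
                dx = dx[:, :, padding:-padding, padding:-padding]
            x._accum(dx)

    return Tensor._make(out, parents, bw)


def conv_transpose2d(
    x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0,
    output_padding: int = 0,
) -> Tensor:
    """Transposed 2D convolution, x (N,Cin,H,W), weight (Cin,Cout,kh,kw).

    Output spatial size: (H-1)*stride - 2*padding + kh + output_padding.
    """
    x = Tensor._lift(x)
    weight = Tensor._lift(weight)
    cin, cout, kh, kw = weight.data.shape
    n, _, h, w = x.data.shape
    hp = (h - 1) * stride + kh
    wp = (w - 1) * stride + kw
    # scatter x into padded output via col2im of the outer product with weight
    dcols = np.einsum("nchw,cokl->noklhw", x.data, weight.data)
    out_full = _col2im(dcols, (n, cout, hp, wp), kh, kw, stride)
    ho = hp - 2 * padding + output_padding
    wo = wp - 2 * padding + output_padding
    out = np.zeros((n, cout, ho, wo), dtype=out_full.dtype)
    crop = out_full[:, :, padding : padding + ho, padding : padding + wo]
    out[:, :, : crop.shape[2], : crop.shape[3]] = crop
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        if bias is not None:
            bias._accum(g.sum(axis=(0, 2, 3)))
        gfull = np.zeros((n, cout, hp, wp), dtype=g.dtype)
        gcrop = g[:, :, : hp - padding, : wp - padding]
        gfull[:, :, padding : padding + gcrop.shape[2], padding : padding + gcrop.shape[3]] = gcrop
        cols = _im2col(gfull, kh, kw, stride)  # (N,Cout,kh,kw,H,W)
        weight._accum(np.einsum("nchw,noklhw->cokl", x.data, cols))
        if x.requires_grad:
            x._accum(np.einsum("cokl,noklhw->nchw", weight.data, cols))

    return Tensor._make(out, parents, bw)


class Adam:
    """Adam optimizer over a list of parameter Tensors.

    ``clip_norm`` rescales the global gradient norm when it exceeds the given
    value (applied in :meth:`step`); None disables clipping.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def _clip(self):
        total = np.sqrt(sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None))
        if total > self.clip_norm and total > 0:
            scale = self.clip_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale  # no in-place: grads may be borrowed

    def step(self):
        if self.clip_norm is not None:
            self._clip()
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
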