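"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine implements exactly the operations the two model branches need:
broadcast arithmetic, matrix products (including batched), ReLU / sigmoid /
log / exp / sqrt, axis reductions, reshaping, concatenation, 2-D convolution
with stride / padding / dilation / groups (im2col), and 3x3 max pooling.
Gradients are accumulated by topological traversal of the recorded graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "max_pool2d", "gather_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _coerce(self, x) -> "Tensor":
        """Wrap an operand; Python scalars adopt this tensor's dtype."""
        if isinstance(x, Tensor):
            return x
        if np.isscalar(x) and np.issubdtype(self.data.dtype, np.inexact):
            return Tensor(np.asarray(x, dtype=self.data.dtype))
        return Tensor(x)

    # -- basics ---------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._result(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._result(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._result(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self
        out = a.data ** p

        def bw(g):
            a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._result(out, (a,), bw)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._result(a.data @ b.data, (a, b), bw)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._result(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def sigmoid(self):
        a = self
        x = a.data
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return Tensor._result(out, (a,), lambda g: a._accum(g * out * (1.0 - out)))

    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._result(out, (a,), lambda g: a._accum(g * out))

    def log(self):
        a = self
        return Tensor._result(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def sqrt(self):
        return self ** 0.5

    # -- reductions / shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            a._accum(np.broadcast_to(g, a.shape).astype(a.data.dtype))

        return Tensor._result(out, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        out = a.data.reshape(*shape)
        return Tensor._result(out, (a,), lambda g: a._accum(g.reshape(a.shape)))

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)
        return Tensor._result(
            a.data.transpose(axes), (a,), lambda g: a._accum(g.transpose(inv))
        )

    def __getitem__(self, idx):
        a = self
        out = a.data[idx]

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._result(out, (a,), bw)

    def log_softmax(self, axis: int = -1):
        shift = self - Tensor(np.max(self.data, axis=axis, keepdims=True))
        return shift - shift.exp().sum(axis=axis, keepdims=True).log()

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._result(out, tuple(tensors), bw)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Pick x[i, idx[i]] for each row i of a 2-D tensor."""
    rows = np.arange(x.shape[0])
    return x[(rows, np.asarray(idx))]


# -- convolution / pooling ----------------------------------------------------


def _im2col(xp: np.ndarray, kh, kw, sh, sw, dh, dw):
    n, c, h, w = xp.shape
    ho = (h - (dh * (kh - 1) + 1)) // sh + 1
    wo = (w - (dw * (kw - 1) + 1)) // sw + 1
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s[0], s[1], s[2] * dh, s[3] * dw, s[2] * sh, s[3] * sw),
        writeable=False,
    )
    return view, ho, wo


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation; x is (N,C,H,W), weight is (Cout, C/groups, kh, kw)."""
    n, c, h, w = x.shape
    cout, cg, kh, kw = weight.shape
    if c != cg * groups:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {cg * groups}")
    og = cout // groups
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, ho, wo = _im2col(xp, kh, kw, stride, stride, dilation, dilation)
    # (N, G, Cg*kh*kw, Ho*Wo)
    cols = np.ascontiguousarray(cols).reshape(n, groups, cg * kh * kw, ho * wo)
    wg = weight.data.reshape(groups, og, cg * kh * kw)
    out = np.matmul(wg, cols)  # (N, G, Og, Ho*Wo)
    out = out.reshape(n, cout, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gflat = g.reshape(n, groups, og, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.matmul(gflat, cols.transpose(0, 1, 3, 2)).sum(axis=0)
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            dcols = np.matmul(wg.transpose(0, 2, 1), gflat)  # (N,G,Cg*kh*kw,HoWo)
            dcols = dcols.reshape(n, c, kh, kw, ho, wo)
            gx = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gx[
                        :,
                        :,
                        i * dilation : i * dilation + stride * ho : stride,
                        j * dilation : j * dilation + stride * wo : stride,
                    ] += dcols[:, :, i, j]
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accum(gx)

    return Tensor._result(out, parents, bw)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Fused batch normalisation over (N,C) or (N,C,H,W), per channel C.

    In training mode batch statistics are used and the running statistics are
    updated in place; in eval mode the running statistics are used.
    """
    axes = (0,) if x.ndim == 2 else (0, 2, 3)
    cshape = (1, -1) if x.ndim == 2 else (1, -1, 1, 1)
    m = np.prod([x.shape[a] for a in axes])
    if training:
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        running_mean *= 1 - momentum
        running_mean += momentum * mu.reshape(-1)
        running_var *= 1 - momentum
        running_var += momentum * var.reshape(-1)
    else:
        mu = running_mean.reshape(cshape)
        var = running_var.reshape(cshape)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    gc = gamma.data.reshape(cshape)
    out = xhat * gc + beta.data.reshape(cshape)

    def bw(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if x.requires_grad:
            scale = (gc * inv_std).astype(x.data.dtype)
            if training:
                gm = g.mean(axis=axes, keepdims=True)
                gxm = (g * xhat).mean(axis=axes, keepdims=True)
                x._accum(scale * (g - gm - xhat * gxm))
            else:
                x._accum(scale * g)

    return Tensor._result(out.astype(x.data.dtype), (x, gamma, beta), bw)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, w = x.shape
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    cols, ho, wo = _im2col(xp, kernel, kernel, stride, stride, 1, 1)
    cols = np.ascontiguousarray(cols).reshape(n, c, kernel * kernel, ho, wo)
    arg = cols.argmax(axis=2)
    out = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]

    def bw(g):
        gx = np.zeros_like(xp)
        for k in range(kernel * kernel):
            i, j = divmod(k, kernel)
            mask = (arg == k) * g
            gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += mask
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        x._accum(gx)

    return Tensor._result(out, (x,), bw)
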