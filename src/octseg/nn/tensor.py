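"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Implements exactly the operations the segmentation network needs: broadcasting
arithmetic, (batched) matrix products, 2-D convolution and transposed
convolution via im2col/col2im, 2x2 max pooling that records argmax indices,
index unpooling, reductions, and numerically stable softmax/log-softmax.
Gradients are hand-derived per operation and validated against central finite
differences in the test suite.

Tensors form a DAG; :meth:`Tensor.backward` runs a topological sort and calls
each node's backward closure, accumulating into ``.grad``.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ---- autograd ------------------------------------------------------------
    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, power(other, -1.0))

    def __pow__(self, e):
        return power(self, e)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# ---- elementwise & arithmetic ------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    return _node(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    return _node(data, (a, b), backward)


def power(a, e: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** e

    def backward(g):
        a._accum(g * e * a.data ** (e - 1.0))

    return _node(data, (a,), backward)


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    data = np.sqrt(a.data)

    def backward(g):
        a._accum(g * 0.5 / np.sqrt(a.data))

    return _node(data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        a._accum(g * data)

    return _node(data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        a._accum(g / a.data)

    return _node(data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        a._accum(g * mask)

    return _node(data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through the interior only."""
    a = _as_tensor(a)
    data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accum(g * mask)

    return _node(data, (a,), backward)


# ---- shape ops ---------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(a.shape))

    return _node(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        a._accum(g.transpose(inv))

    return _node(data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accum(full)

    return _node(data, (a,), backward)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return _node(data, tuple(tensors), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, ax)
        a._accum(np.broadcast_to(g, a.shape).copy())

    return _node(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


# ---- linear algebra ----------------------------------------------------------

def matmul(a, b) -> Tensor:
    """Matrix product with numpy batch-broadcast semantics."""
    a, b = _as_tensor(a), _as_tensor(b)
    data = np.matmul(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.shape))

    return _node(data, (a, b), backward)


# ---- softmax family ----------------------------------------------------------

def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        a._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    return _node(s, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    shifted = a.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse
    sm = np.exp(out)

    def backward(g):
        a._accum(g - sm * g.sum(axis=axis, keepdims=True))

    return _node(out, (a,), backward)


def normalize(a, axes: tuple, eps: float = 1e-5) -> Tensor:
    """Fused (x - mean) / sqrt(var + eps) over ``axes`` (single op, so the
    graph retains only the normalized output and the inverse std)."""
    a = _as_tensor(a)
    mu = a.data.mean(axis=axes, keepdims=True)
    var = a.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv_std

    def backward(g):
        m = np.mean(g, axis=axes, keepdims=True)
        mx = np.mean(g * xhat, axis=axes, keepdims=True)
        a._accum(inv_std * (g - m - xhat * mx))

    return _node(xhat, (a,), backward)


# ---- convolution -------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int,
            oh: int, ow: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw]
    return cols


def _col2im(cols: np.ndarray, hp: int, wp: int, kh: int, kw: int,
            sh: int, sw: int) -> np.ndarray:
    n, c, _, _, oh, ow = cols.shape
    x = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += cols[:, :, i, j]
    return x


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation; x (N,C,H,W), w (O,C,kh,kw), b (O,)."""
    x, w = _as_tensor(x), _as_tensor(w)
    b = _as_tensor(b) if b is not None else None
    n, c, h, wdt = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {c2}")
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    oh = (hp - kh) // s + 1
    ow = (wp - kw) // s + 1
    pointwise = kh == kw == 1 and s == 1
    if pointwise:
        cols2 = xp.reshape(n, c, oh * ow)      # no copy for 1x1 kernels
    else:
        cols2 = _im2col(xp, kh, kw, s, s, oh, ow).reshape(n, c * kh * kw,
                                                          oh * ow)
    w2 = w.data.reshape(o, c * kh * kw)
    out = np.matmul(w2, cols2).reshape(n, o, oh, ow)
    if b is not None:
        out += b.data.reshape(1, o, 1, 1)

    def backward(g):
        g2 = g.reshape(n, o, oh * ow)
        if w.requires_grad:
            gw = np.matmul(g2, cols2.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(w2.T, g2)
            if pointwise:
                gx = gcols.reshape(n, c, oh, ow)
            else:
                gx = _col2im(gcols.reshape(n, c, kh, kw, oh, ow),
                             hp, wp, kh, kw, s, s)
            if padding:
                gx = gx[:, :, padding:hp - padding, padding:wp - padding]
            x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def conv_transpose2d(x, w, b=None, stride: int = 2) -> Tensor:
    """Transposed convolution; x (N,C,H,W), w (C,O,kh,kw), output
    ((H-1)*stride + kh). With kh=stride this exactly doubles extent."""
    x, w = _as_tensor(x), _as_tensor(w)
    b = _as_tensor(b) if b is not None else None
    n, c, h, wdt = x.shape
    c2, o, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv_transpose2d channel mismatch: input {c}, kernel {c2}")
    s = stride
    oh = (h - 1) * s + kh
    ow = (wdt - 1) * s + kw
    w2 = w.data.reshape(c, o * kh * kw)
    x2 = x.data.reshape(n, c, h * wdt)
    ycols = np.matmul(w2.T, x2).reshape(n, o, kh, kw, h, wdt)
    out = _col2im(ycols, oh, ow, kh, kw, s, s)
    if b is not None:
        out += b.data.reshape(1, o, 1, 1)

    def backward(g):
        gcols = _im2col(g, kh, kw, s, s, h, wdt).reshape(n, o * kh * kw, h * wdt)
        if x.requires_grad:
            gx = np.matmul(w2, gcols).reshape(x.shape)
            x._accum(gx)
        if w.requires_grad:
            gw = np.matmul(gcols, x2.transpose(0, 2, 1)).sum(axis=0)  # (o*kh*kw, c)
            w._accum(gw.T.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


# ---- pooling -----------------------------------------------------------------

def max_pool2d(x) -> tuple[Tensor, np.ndarray]:
    """2x2, stride-2 max pooling.

    Returns the pooled tensor and an int array (N,C,H/2,W/2) of window-local
    argmax positions in {0,1,2,3} (row-major within each 2x2 window).
    """
    x = _as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2d requires even extent, got {h}x{w}")
    oh, ow = h // 2, w // 2
    win = x.data.reshape(n, c, oh, 2, ow, 2).transpose(0, 1, 2, 4, 3, 5) \
        .reshape(n, c, oh, ow, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gw = np.zeros((n, c, oh, ow, 4), dtype=g.dtype)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = gw.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5) \
            .reshape(n, c, h, w)
        x._accum(gx)

    return _node(out, (x,), backward), idx


def max_unpool2d(x, indices: np.ndarray) -> Tensor:
    """Scatter each value to its recorded argmax position; zeros elsewhere."""
    x = _as_tensor(x)
    n, c, oh, ow = x.shape
    if indices.shape != x.shape:
        raise ValueError(
            f"unpool indices shape {indices.shape} does not match input {x.shape}")
    win = np.zeros((n, c, oh, ow, 4), dtype=x.dtype)
    np.put_along_axis(win, indices[..., None], x.data[..., None], axis=-1)
    out = win.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5) \
        .reshape(n, c, oh * 2, ow * 2)

    def backward(g):
        gwin = g.reshape(n, c, oh, 2, ow, 2).transpose(0, 1, 2, 4, 3, 5) \
            .reshape(n, c, oh, ow, 4)
        gx = np.take_along_axis(gwin, indices[..., None], axis=-1)[..., 0]
        x._accum(gx)

    return _node(out, (x,), backward)
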