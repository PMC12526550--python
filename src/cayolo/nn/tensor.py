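"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations needed by the detector: elementwise
arithmetic, activations, reductions, shape manipulation, 2-D convolution
(im2col + BLAS), max-pooling and nearest-neighbour upsampling.  Tensors
carry whatever dtype their data has; parameters default to float32 but
tests may build float64 graphs for tight oracle comparisons.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Parameter", "astensor", "add", "mul", "matmul", "relu",
    "sigmoid", "log_sigmoid", "silu", "exp", "log", "sqrt", "clip",
    "minimum", "maximum", "arctan", "tsum", "tmean", "reshape",
    "transpose", "concat", "conv2d", "max_pool2d", "upsample_nearest2",
    "softmax", "log_softmax", "gather_last", "pad_hw",
]


class Tensor:
    """A node in the autodiff graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- graph ----------------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def detach(self):
        return Tensor(self.data, requires_grad=False)

    # -- conveniences ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def __add__(self, o):
        return add(self, o)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, o):
        if isinstance(o, (int, float)) and not isinstance(o, bool):
            return add(self, -o)
        return add(self, mul(astensor(o), -1.0))

    def __rsub__(self, o):
        return add(astensor(o) if isinstance(o, Tensor) else o,
                    mul(self, -1.0))

    def __mul__(self, o):
        return mul(self, o)

    __rmul__ = __mul__

    def __truediv__(self, o):
        if isinstance(o, (int, float)) and not isinstance(o, bool):
            return mul(self, 1.0 / o)
        return mul(self, power(astensor(o), -1.0))

    def __rtruediv__(self, o):
        return mul(astensor(o), power(self, -1.0))

    def __pow__(self, k):
        return power(self, k)

    def __matmul__(self, o):
        return matmul(self, o)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)


class Parameter(Tensor):
    """Trainable tensor; defaults to float32 storage."""

    def __init__(self, data, dtype=np.float32):
        super().__init__(np.asarray(data, dtype=dtype), requires_grad=True)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise ---------------------------------------------------------

def _pyscalar(x):
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def add(a, b):
    if _pyscalar(a):
        a, b = b, a
    if _pyscalar(b):
        # keep python scalars weak so float32 graphs stay float32
        a = astensor(a)
        out_data = a.data + b

        def bw_s(g):
            if a.requires_grad:
                a._accum(g)

        return _make(out_data, (a,), bw_s)
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bw)


def mul(a, b):
    if _pyscalar(a):
        a, b = b, a
    if _pyscalar(b):
        a = astensor(a)
        out_data = a.data * b

        def bw_s(g):
            if a.requires_grad:
                a._accum(g * b)

        return _make(out_data, (a,), bw_s)
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bw)


def power(a, k):
    a = astensor(a)
    if isinstance(k, Tensor):
        k = float(k.data)
    out_data = a.data ** k

    def bw(g):
        if a.requires_grad:
            a._accum(g * k * a.data ** (k - 1))

    return _make(out_data, (a,), bw)


def exp(a):
    a = astensor(a)
    out_data = np.exp(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g * out_data)

    return _make(out_data, (a,), bw)


def log(a):
    a = astensor(a)
    out_data = np.log(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return _make(out_data, (a,), bw)


def sqrt(a):
    return power(a, 0.5)


def relu(a):
    a = astensor(a)
    out_data = np.maximum(a.data, 0)

    def bw(g):
        if a.requires_grad:
            a._accum(g * (a.data > 0))

    return _make(out_data, (a,), bw)


def sigmoid(a):
    from scipy.special import expit

    a = astensor(a)
    out_data = expit(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bw)


def log_sigmoid(a):
    """Numerically stable log(sigmoid(x)) = -softplus(-x)."""
    a = astensor(a)
    x = a.data
    out_data = np.minimum(x, 0) - np.log1p(np.exp(-np.abs(x)))

    def bw(g):
        if a.requires_grad:
            from scipy.special import expit

            # d/dx log sigmoid(x) = sigmoid(-x)
            a._accum(g * expit(-x))

    return _make(out_data, (a,), bw)


def silu(a):
    return mul(a, sigmoid(a))


def arctan(a):
    a = astensor(a)
    out_data = np.arctan(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g / (1.0 + a.data ** 2))

    return _make(out_data, (a,), bw)


def clip(a, lo, hi):
    """Clamp; gradient passes only where the input is strictly inside."""
    a = astensor(a)
    out_data = np.clip(a.data, lo, hi)

    def bw(g):
        if a.requires_grad:
            a._accum(g * ((a.data > lo) & (a.data < hi)))

    return _make(out_data, (a,), bw)


def minimum(a, b):
    a, b = astensor(a), astensor(b)
    out_data = np.minimum(a.data, b.data)

    def bw(g):
        mask = a.data <= b.data
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.data.shape))

    return _make(out_data, (a, b), bw)


def maximum(a, b):
    a, b = astensor(a), astensor(b)
    out_data = np.maximum(a.data, b.data)

    def bw(g):
        mask = a.data >= b.data
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.data.shape))

    return _make(out_data, (a, b), bw)


# -- reductions / shape ---------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape))
        else:
            g2 = g if keepdims else np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g2, a.data.shape))

    return _make(out_data, (a,), bw)


def tmean(a, axis=None, keepdims=False):
    a = astensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape):
    a = astensor(a)
    out_data = a.data.reshape(shape)
    in_shape = a.data.shape

    def bw(g):
        if a.requires_grad:
            a._accum(g.reshape(in_shape))

    return _make(out_data, (a,), bw)


def transpose(a, axes):
    a = astensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bw(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    return _make(out_data, (a,), bw)


def concat(tensors, axis=0):
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _make(out_data, tuple(tensors), bw)


def getitem(a, idx):
    a = astensor(a)
    out_data = a.data[idx]

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

    return _make(out_data, (a,), bw)


def gather_last(a, idx):
    """Select a[..., idx[...]] along the last axis (integer gather)."""
    a = astensor(a)
    idx = np.asarray(idx)
    out_data = np.take_along_axis(a.data, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.put_along_axis(full, idx[..., None], g[..., None], axis=-1)
            a._accum(full)

    return _make(out_data, (a,), bw)


def matmul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), bw)


def softmax(a, axis=-1):
    a = astensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))  # constant shift
    e = exp(a - shift)
    return e / tsum(e, axis=axis, keepdims=True)


def log_softmax(a, axis=-1):
    a = astensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    z = a - shift
    return z - log(tsum(exp(z), axis=axis, keepdims=True))


# -- spatial ops ----------------------------------------------------------

def pad_hw(a, p):
    """Zero-pad the last two axes by p on each side."""
    a = astensor(a)
    if p == 0:
        return a
    pads = [(0, 0)] * (a.data.ndim - 2) + [(p, p), (p, p)]
    out_data = np.pad(a.data, pads)

    def bw(g):
        if a.requires_grad:
            sl = (Ellipsis, slice(p, -p), slice(p, -p))
            a._accum(g[sl])

    return _make(out_data, (a,), bw)


def _im2col(x, kh, kw, sh, sw):
    """x: (N, C, H, W) already padded -> (N, OH, OW, C, kh, kw) copy."""
    n, c, h, w = x.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, oh, ow, c, kh, kw), (s0, s2 * sh, s3 * sw, s1, s2, s3))
    return np.ascontiguousarray(view), oh, ow


def _col2im(gcols, xshape, kh, kw, sh, sw):
    """Inverse scatter of _im2col. gcols: (N, OH, OW, C, kh, kw)."""
    n, c, h, w = xshape
    _, oh, ow = gcols.shape[0], gcols.shape[1], gcols.shape[2]
    gx = np.zeros(xshape, dtype=gcols.dtype)
    for i in range(kh):
        hi = i + sh * oh
        for j in range(kw):
            wj = j + sw * ow
            gx[:, :, i:hi:sh, j:wj:sw] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return gx


def conv2d(x, w, b=None, stride=1, padding=0):
    """2-D cross-correlation. x: (N,C,H,W); w: (Cout,Cin,kh,kw); b: (Cout,)."""
    x = astensor(x)
    w = astensor(w)
    if b is not None:
        b = astensor(b)
    xp = pad_hw(x, padding)
    n, cin, hp, wp = xp.data.shape
    cout, _, kh, kw = w.data.shape
    cols, oh, ow = _im2col(xp.data, kh, kw, stride, stride)
    mat = cols.reshape(n * oh * ow, cin * kh * kw)
    wmat = w.data.reshape(cout, -1)
    out_data = mat @ wmat.T
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)

    parents = (xp, w) if b is None else (xp, w, b)

    def bw(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, cout)
        if w.requires_grad:
            w._accum((gmat.T @ mat).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if xp.requires_grad:
            gcols = (gmat @ wmat).reshape(n, oh, ow, cin, kh, kw)
            xp._accum(_col2im(gcols, xp.data.shape, kh, kw, stride, stride))

    return _make(out_data, parents, bw)


def max_pool2d(x, k, stride=1, padding=0):
    x = astensor(x)
    src = x
    if padding:
        # -inf padding so border maxima come from real cells
        data = np.pad(x.data, [(0, 0), (0, 0), (padding, padding), (padding, padding)],
                      constant_values=-np.inf)
    else:
        data = x.data
    n, c, hp, wp = data.shape
    cols, oh, ow = _im2col(data, k, k, stride, stride)
    flat = cols.reshape(n, oh, ow, c, k * k)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    out_data = out_data.transpose(0, 3, 1, 2)

    def bw(g):
        if not src.requires_grad:
            return
        gx = np.zeros((n, c, hp, wp), dtype=g.dtype)
        ii, jj = np.divmod(arg, k)  # (N, OH, OW, C)
        nn, oo_h, oo_w, cc = np.indices(arg.shape)
        rows = oo_h * stride + ii
        colsx = oo_w * stride + jj
        np.add.at(gx, (nn, cc, rows, colsx), g.transpose(0, 2, 3, 1))
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        src._accum(gx)

    return _make(out_data, (src,), bw)


def upsample_nearest2(x):
    x = astensor(x)
    out_data = x.data.repeat(2, axis=-2).repeat(2, axis=-1)

    def bw(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return _make(out_data, (x,), bw)
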