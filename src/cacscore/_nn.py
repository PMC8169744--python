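"""Minimal reverse-mode autograd and layer toolkit on NumPy.

Provides exactly the operations the slice-wise segmentation model needs:
2-D convolution (with channel groups), 4x4 stride-2 transposed convolution,
ReLU / sigmoid / per-pixel channel softmax, channel concatenation,
squeeze-and-excitation gating, and the reductions used by the Dice and
cross-entropy losses.  Gradients are hand-derived per op and validated by
finite differences in the test suite.

All tensors are float64 ``(N, C, H, W)`` unless noted.  This is a desk-scale
engine: clarity and correctness over throughput.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "add",
    "mul",
    "div",
    "concat_channels",
    "relu",
    "sigmoid",
    "log",
    "softmax_channels",
    "sum_all",
    "global_avg_pool",
    "conv2d",
    "conv_transpose2d",
    "group_norm",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "GroupNorm",
    "SEBlock",
]


# ---------------------------------------------------------------------------
# autograd core
# ---------------------------------------------------------------------------

class Tensor:
    """A NumPy array plus the closure that back-propagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        """Reverse-mode sweep seeded with d(self)/d(self) = 1 (scalar only)."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # Convenience arithmetic (scalar or tensor operands).
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _as_tensor(-1.0))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)


def parameter(data):
    return Tensor(data, requires_grad=True)


def constant(data):
    return Tensor(data, requires_grad=False)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _binary(a, b, out_data, da_fn, db_fn):
    needs = a.requires_grad or b.requires_grad
    out = Tensor(out_data, requires_grad=needs, parents=(a, b) if needs else ())

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(da_fn(g), a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(db_fn(g), b.data.shape))

    if needs:
        out._backward = backward
    return out


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data * b.data,
                   lambda g: g * b.data, lambda g: g * a.data)


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data / b.data,
                   lambda g: g / b.data,
                   lambda g: -g * a.data / (b.data ** 2))


def _unary(a, out_data, da_fn):
    out = Tensor(out_data, requires_grad=a.requires_grad,
                 parents=(a,) if a.requires_grad else ())
    if a.requires_grad:
        out._backward = lambda g: a._accum(da_fn(g))
    return out


def relu(a):
    m = a.data > 0
    return _unary(a, a.data * m, lambda g: g * m)


def sigmoid(a):
    y = 1.0 / (1.0 + np.exp(-a.data))
    return _unary(a, y, lambda g: g * y * (1.0 - y))


def log(a):
    return _unary(a, np.log(a.data), lambda g: g / a.data)


def softmax_channels(a):
    """Softmax over axis 1 (the channel axis), per pixel."""
    z = a.data - a.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=1, keepdims=True)
    return _unary(a, y, lambda g: y * (g - (g * y).sum(axis=1, keepdims=True)))


def sum_all(a):
    out_data = np.asarray(a.data.sum())
    return _unary(a, out_data, lambda g: np.full_like(a.data, float(g)))


def global_avg_pool(a):
    """Mean over the spatial axes, keepdims -> (N, C, 1, 1)."""
    n = a.data.shape[2] * a.data.shape[3]
    y = a.data.mean(axis=(2, 3), keepdims=True)
    return _unary(a, y, lambda g: np.broadcast_to(g / n, a.data.shape).copy())


def concat_channels(tensors):
    tensors = [_as_tensor(t) for t in tensors]
    needs = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1),
                 requires_grad=needs, parents=tuple(tensors) if needs else ())

    def backward(g):
        ofs = 0
        for t in tensors:
            c = t.data.shape[1]
            if t.requires_grad:
                t._accum(g[:, ofs:ofs + c])
            ofs += c

    if needs:
        out._backward = backward
    return out


def group_norm(x, gamma, beta, n_groups, eps=1e-5):
    """Group normalization over (C/G, H, W) per sample, with affine params
    ``gamma``/``beta`` of shape (C,)."""
    n, c, h, w = x.data.shape
    if c % n_groups:
        raise ValueError("channels not divisible by n_groups")
    m = (c // n_groups) * h * w
    xg = x.data.reshape(n, n_groups, m)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(n, c, h, w)
    ydata = xhat * gamma.data.reshape(1, c, 1, 1) \
        + beta.data.reshape(1, c, 1, 1)
    parents = (x, gamma, beta)
    needs = any(p.requires_grad for p in parents)
    out = Tensor(ydata, requires_grad=needs, parents=parents if needs else ())

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = (g * gamma.data.reshape(1, c, 1, 1)).reshape(n, n_groups, m)
            xh = xhat.reshape(n, n_groups, m)
            dx = inv / m * (m * dxhat
                            - dxhat.sum(axis=2, keepdims=True)
                            - xh * (dxhat * xh).sum(axis=2, keepdims=True))
            x._accum(dx.reshape(n, c, h, w))

    if needs:
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution primitives (im2col / col2im)
# ---------------------------------------------------------------------------

def _im2col(xp, k, stride):
    # xp: padded input (N, C, Hp, Wp) -> cols (N, C*k*k, Ho*Wo)
    v = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = v.shape[:4]
    cols = v.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols, padded_shape, k, stride, ho, wo):
    n, c, hp, wp = padded_shape
    x = np.zeros(padded_shape, dtype=cols.dtype)
    cols6 = cols.reshape(n, c, k, k, ho, wo)
    for ki in range(k):
        for kj in range(k):
            x[:, :, ki:ki + stride * ho:stride,
              kj:kj + stride * wo:stride] += cols6[:, :, ki, kj]
    return x


def _conv_fwd(x, w, stride, pad):
    # x (N,C,H,W), w (O,C,k,k) -> y (N,O,Ho,Wo)
    k = w.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols, ho, wo = _im2col(xp, k, stride)
    y = np.matmul(w.reshape(w.shape[0], -1), cols)
    return y.reshape(x.shape[0], w.shape[0], ho, wo), cols


def _conv_bwd_x(dy, w, x_shape, stride, pad):
    n, c, h, wdt = x_shape
    k = w.shape[2]
    ho, wo = dy.shape[2], dy.shape[3]
    dyf = dy.reshape(n, dy.shape[1], ho * wo)
    dcols = np.matmul(w.reshape(w.shape[0], -1).T, dyf)
    dxp = _col2im(dcols, (n, c, h + 2 * pad, wdt + 2 * pad), k, stride, ho, wo)
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def _conv_bwd_w(x, dy, w_shape, stride, pad):
    k = w_shape[2]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols, ho, wo = _im2col(xp, k, stride)
    dyf = dy.reshape(dy.shape[0], dy.shape[1], ho * wo)
    dw = np.einsum("nol,ncl->oc", dyf, cols, optimize=True)
    return dw.reshape(w_shape)


def _grouped(fn, n_groups, x_parts, w_parts, *args):
    return [fn(xg, wg, *args) for xg, wg in zip(x_parts, w_parts)]


def conv2d(x, w, b=None, stride=1, pad=1, groups=1):
    """2-D convolution; ``w`` is (C_out, C_in/groups, k, k)."""
    x, w = _as_tensor(x), _as_tensor(w)
    cin, cout = x.data.shape[1], w.data.shape[0]
    if cin % groups or cout % groups:
        raise ValueError("channels not divisible by groups")
    xs = np.split(x.data, groups, axis=1)
    ws = np.split(w.data, groups, axis=0)
    ys = [_conv_fwd(xg, wg, stride, pad)[0] for xg, wg in zip(xs, ws)]
    ydata = np.concatenate(ys, axis=1)
    if b is not None:
        b = _as_tensor(b)
        ydata = ydata + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) + ((b,) if b is not None else ())
    needs = any(p.requires_grad for p in parents)
    out = Tensor(ydata, requires_grad=needs, parents=parents if needs else ())

    def backward(g):
        gs = np.split(g, groups, axis=1)
        if x.requires_grad:
            dx = np.concatenate(
                [_conv_bwd_x(gg, wg, xg.shape, stride, pad)
                 for gg, wg, xg in zip(gs, ws, xs)], axis=1)
            x._accum(dx)
        if w.requires_grad:
            dw = np.concatenate(
                [_conv_bwd_w(xg, gg, wg.shape, stride, pad)
                 for xg, gg, wg in zip(xs, gs, ws)], axis=0)
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    if needs:
        out._backward = backward
    return out


def conv_transpose2d(x, w, b=None, stride=2, pad=1):
    """Transposed convolution; ``w`` is (C_in, C_out, k, k).

    With the default 4x4 kernel, stride 2, pad 1 the spatial size doubles
    exactly.  Forward is the adjoint of the matching strided convolution.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    n, cin, h, wdt = x.data.shape
    cout, k = w.data.shape[1], w.data.shape[2]
    hout = (h - 1) * stride + k - 2 * pad
    wout = (wdt - 1) * stride + k - 2 * pad
    ydata = _conv_bwd_x(x.data, w.data, (n, cout, hout, wout), stride, pad)
    if b is not None:
        b = _as_tensor(b)
        ydata = ydata + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) + ((b,) if b is not None else ())
    needs = any(p.requires_grad for p in parents)
    out = Tensor(ydata, requires_grad=needs, parents=parents if needs else ())

    def backward(g):
        if x.requires_grad:
            x._accum(_conv_fwd(g, w.data, stride, pad)[0])
        if w.requires_grad:
            w._accum(_conv_bwd_w(g, x.data, w.data.shape, stride, pad))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    if needs:
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    """Parameter container; submodules discovered through attributes."""

    def parameters(self, prefix=""):
        """Dict of dotted-name -> Tensor for every trainable parameter."""
        out = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.parameters(prefix=f"{key}.{i}."))
        return out

    def zero_grad(self):
        for p in self.parameters().values():
            p.zero_grad()


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, rng, cin, cout, k=3, stride=1, pad=None, groups=1,
                 bias=True):
        if pad is None:
            pad = k // 2
        self.stride, self.pad, self.groups = stride, pad, groups
        fan_in = (cin // groups) * k * k
        self.w = parameter(_he_init(rng, (cout, cin // groups, k, k), fan_in))
        self.b = parameter(np.zeros(cout)) if bias else None

    def __call__(self, x):
        return conv2d(x, self.w, self.b, self.stride, self.pad, self.groups)


class ConvTranspose2d(Module):
    def __init__(self, rng, cin, cout, k=4, stride=2, pad=1, bias=True):
        self.stride, self.pad = stride, pad
        self.w = parameter(_he_init(rng, (cin, cout, k, k), cin * k * k))
        self.b = parameter(np.zeros(cout)) if bias else None

    def __call__(self, x):
        return conv_transpose2d(x, self.w, self.b, self.stride, self.pad)


class GroupNorm(Module):
    """Per-sample group normalization with learnable gain and shift."""

    def __init__(self, channels, n_groups=None):
        self.n_groups = n_groups or int(np.gcd(channels, 8))
        self.gamma = parameter(np.ones(channels))
        self.beta = parameter(np.zeros(channels))

    def __call__(self, x):
        return group_norm(x, self.gamma, self.beta, self.n_groups)


class SEBlock(Module):
    """Squeeze-and-excitation channel gate (global pool -> bottleneck MLP)."""

    def __init__(self, rng, channels, reduction=16):
        hidden = max(1, channels // reduction)
        self.fc1 = Conv2d(rng, channels, hidden, k=1, pad=0)
        self.fc2 = Conv2d(rng, hidden, channels, k=1, pad=0)

    def __call__(self, x):
        s = global_avg_pool(x)
        gate = sigmoid(self.fc2(relu(self.fc1(s))))
        return mul(x, gate)
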