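"""Tape-based reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray; every op returns a new Tensor
holding a closure that maps the output gradient to input-gradient
accumulations.  ``backward()`` runs the tape in reverse topological order.
Graph construction is skipped entirely inside :func:`no_grad` or when no
input requires gradients, so inference costs no extra memory.

Convolution uses the shift-and-matmul formulation: for each kernel offset
the strided input slice is contracted with the corresponding weight slab.
This keeps memory at O(activations) (no im2col buffer) and gives an exact
transpose for the backward pass.  Grouped and depthwise convolutions are
handled without Python loops over channels.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_grad_enabled = True


@contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free the tape as we go

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, powi(other, -1.0))
        return mul(self, 1.0 / np.asarray(other, dtype=np.float32))

    def __rtruediv__(self, other):
        return mul(powi(self, -1.0), other)

    def __pow__(self, k):
        return powi(self, k)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _make(data, inputs, backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(t.requires_grad for t in inputs):
        out.requires_grad = True
        out._prev = tuple(inputs)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient down to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise --------------------------------------------------------
def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def powi(a, k) -> Tensor:
    a = _as_tensor(a)
    k = float(k)
    out_data = a.data**k

    def backward(g):
        _accum(a, g * k * a.data ** (k - 1.0))

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp; gradient is zero outside [lo, hi] (subgradient convention)."""
    a = _as_tensor(a)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        _accum(a, g * mask)

    return _make(np.clip(a.data, lo, hi), (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def _expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(a) -> Tensor:
    """Numerically stable logistic; output clamped to the open interval
    [1e-7, 1 - 1e-7] so float32 saturation never emits exact 0 or 1."""
    a = _as_tensor(a)
    s = np.clip(_expit(a.data), 1e-7, 1.0 - 1e-7)

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    return _make(s, (a,), backward)


def silu(a) -> Tensor:
    """x * sigmoid(x) (swish)."""
    a = _as_tensor(a)
    s = _expit(a.data)

    def backward(g):
        _accum(a, g * (s + a.data * s * (1.0 - s)))

    return _make(a.data * s, (a,), backward)


# -- reductions ---------------------------------------------------------
def tsum(a, axes=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axes, keepdims=keepdims)

    def backward(g):
        if axes is not None and not keepdims:
            g = np.expand_dims(g, axes)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a, axes=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.mean(axis=axes, keepdims=keepdims)
    scale = out_data.size / a.data.size

    def backward(g):
        if axes is not None and not keepdims:
            g = np.expand_dims(g, axes)
        _accum(a, np.broadcast_to(g, a.data.shape) * scale)

    return _make(out_data, (a,), backward)


# -- structural ---------------------------------------------------------
def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def upsample_nearest2x(a) -> Tensor:
    a = _as_tensor(a)
    n, c, h, w = a.data.shape

    def backward(g):
        _accum(a, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _make(a.data.repeat(2, axis=2).repeat(2, axis=3), (a,), backward)


# -- convolution and pooling --------------------------------------------
def _pad_hw(x: np.ndarray, ph: int, pw: int, value: float = 0.0) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=value)


def conv2d(x, w, b=None, stride: int = 1, padding: tuple[int, int] | int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, with grouped/depthwise support.

    ``w`` has shape (out_ch, in_ch // groups, kh, kw).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    if b is not None:
        b = _as_tensor(b)
    s = stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    n, cin, h, wd = x.data.shape
    cout, cg, kh, kw = w.data.shape
    if cin % groups or cout % groups or cg * groups != cin:
        raise ValueError(f"incompatible conv shapes: x {x.data.shape}, w {w.data.shape}, groups {groups}")
    oh = (h + 2 * ph - kh) // s + 1
    ow = (wd + 2 * pw - kw) // s + 1
    if oh <= 0 or ow <= 0:
        raise ValueError(f"conv output would be empty for input {h}x{wd}, kernel {kh}x{kw}")
    xp = _pad_hw(x.data, ph, pw)
    og = cout // groups
    depthwise = groups == cin and cg == 1

    if depthwise:
        out = np.zeros((n, cout, oh, ow), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + (oh - 1) * s + 1 : s, j : j + (ow - 1) * s + 1 : s]
                out += xs * w.data[:, 0, i, j][None, :, None, None]
    elif groups == 1:
        out = np.zeros((n, cout, oh, ow), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + (oh - 1) * s + 1 : s, j : j + (ow - 1) * s + 1 : s]
                # (n, c, oh, ow) x (o, c) -> (n, o, oh, ow)
                out += np.einsum("nchw,oc->nohw", xs, w.data[:, :, i, j], optimize=True)
    else:
        xg = xp.reshape(n, groups, cg, *xp.shape[2:])
        wg = w.data.reshape(groups, og, cg, kh, kw)
        outg = np.zeros((n, groups, og, oh, ow), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                xs = xg[:, :, :, i : i + (oh - 1) * s + 1 : s, j : j + (ow - 1) * s + 1 : s]
                outg += np.einsum("ngchw,goc->ngohw", xs, wg[:, :, :, i, j], optimize=True)
        out = outg.reshape(n, cout, oh, ow)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(g):
        gxp = np.zeros_like(xp) if x.requires_grad else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        if depthwise:
            for i in range(kh):
                for j in range(kw):
                    sl = (slice(None), slice(None), slice(i, i + (oh - 1) * s + 1, s), slice(j, j + (ow - 1) * s + 1, s))
                    if gw is not None:
                        gw[:, 0, i, j] = (g * xp[sl]).sum(axis=(0, 2, 3))
                    if gxp is not None:
                        gxp[sl] += g * w.data[:, 0, i, j][None, :, None, None]
        elif groups == 1:
            for i in range(kh):
                for j in range(kw):
                    sl = (slice(None), slice(None), slice(i, i + (oh - 1) * s + 1, s), slice(j, j + (ow - 1) * s + 1, s))
                    if gw is not None:
                        gw[:, :, i, j] = np.einsum("nohw,nchw->oc", g, xp[sl], optimize=True)
                    if gxp is not None:
                        gxp[sl] += np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
        else:
            gr = g.reshape(n, groups, og, oh, ow)
            xg = xp.reshape(n, groups, cg, *xp.shape[2:])
            gxg = gxp.reshape(n, groups, cg, *xp.shape[2:]) if gxp is not None else None
            gwg = gw.reshape(groups, og, cg, kh, kw) if gw is not None else None
            for i in range(kh):
                for j in range(kw):
                    sl = (slice(None), slice(None), slice(None), slice(i, i + (oh - 1) * s + 1, s), slice(j, j + (ow - 1) * s + 1, s))
                    if gwg is not None:
                        gwg[:, :, :, i, j] = np.einsum("ngohw,ngchw->goc", gr, xg[sl], optimize=True)
                    if gxg is not None:
                        gxg[sl] += np.einsum("ngohw,goc->ngchw", gr, wg[:, :, :, i, j], optimize=True)
        if gw is not None:
            _accum(w, gw)
        if gxp is not None:
            gx = gxp[:, :, ph : ph + h, pw : pw + wd] if (ph or pw) else gxp
            _accum(x, gx)
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))

    inputs = (x, w) if b is None else (x, w, b)
    return _make(out, inputs, backward)


def maxpool2d(x, kernel: int = 2, stride: int | None = None, padding: int = 0) -> Tensor:
    x = _as_tensor(x)
    s = stride or kernel
    n, c, h, w = x.data.shape
    oh = (h + 2 * padding - kernel) // s + 1
    ow = (w + 2 * padding - kernel) // s + 1
    xp = _pad_hw(x.data, padding, padding, value=-np.inf)
    out = np.full((n, c, oh, ow), -np.inf, dtype=np.float32)
    for i in range(kernel):
        for j in range(kernel):
            np.maximum(out, xp[:, :, i : i + (oh - 1) * s + 1 : s, j : j + (ow - 1) * s + 1 : s], out=out)

    def backward(g):
        gxp = np.zeros_like(xp)
        remaining = np.ones_like(out, dtype=bool)  # route each output's grad to one argmax
        for i in range(kernel):
            for j in range(kernel):
                sl = (slice(None), slice(None), slice(i, i + (oh - 1) * s + 1, s), slice(j, j + (ow - 1) * s + 1, s))
                hit = (xp[sl] == out) & remaining
                gxp[sl] += g * hit
                remaining &= ~hit
        gx = gxp[:, :, padding : padding + h, padding : padding + w] if padding else gxp
        _accum(x, gx)

    return _make(out, (x,), backward)


def avgpool2d(x, kernel: int = 2, stride: int | None = None) -> Tensor:
    x = _as_tensor(x)
    s = stride or kernel
    n, c, h, w = x.data.shape
    oh = (h - kernel) // s + 1
    ow = (w - kernel) // s + 1
    out = np.zeros((n, c, oh, ow), dtype=np.float32)
    for i in range(kernel):
        for j in range(kernel):
            out += x.data[:, :, i : i + (oh - 1) * s + 1 : s, j : j + (ow - 1) * s + 1 : s]
    out /= kernel * kernel

    def backward(g):
        gx = np.zeros_like(x.data)
        gk = g / (kernel * kernel)
        for i in range(kernel):
            for j in range(kernel):
                gx[:, :, i : i + (oh - 1) * s + 1 : s, j : j + (ow - 1) * s + 1 : s] += gk
        _accum(x, gx)

    return _make(out, (x,), backward)
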