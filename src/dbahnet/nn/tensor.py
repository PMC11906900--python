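"""A compact reverse-mode automatic-differentiation core on NumPy arrays.

Tensors wrap float32 ndarrays and record a computation graph; ``backward()``
runs reverse-mode accumulation over a topological ordering.  The op set is
exactly what a volumetric attention/convolution network needs: broadcasting
arithmetic, matmul, fused softmax/layer-norm/GELU/sigmoid, strided 3D
convolution and transposed convolution (implemented as kernel-offset loops so
no im2col buffer is ever materialised), slicing, padding, concatenation and
cyclic rolls for shifted-window attention.

Design notes
------------
* float32 end to end; gradients are float32 as well.
* A global switch (:class:`no_grad`) disables graph recording for inference.
* Gradients accumulate (`+=`), so shared subexpressions are handled naturally.
"""

from __future__ import annotations

import contextlib
import math

import numpy as np
from scipy.special import erf

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the ``with`` block."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray):
        """Accumulate a gradient that may alias another array (copies)."""
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32)
        else:
            self.grad += g

    def _accum_owned(self, g: np.ndarray):
        """Accumulate a freshly-allocated float32 gradient without copying.

        Callers must guarantee `g` is not aliased elsewhere.
        """
        if self.grad is None:
            self.grad = g
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _node(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _node(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum_owned(
                        np.ascontiguousarray(_unbroadcast(g * other.data,
                                                          self.data.shape)))
                if other.requires_grad:
                    other._accum_owned(
                        np.ascontiguousarray(_unbroadcast(g * self.data,
                                                          other.data.shape)))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def __matmul__(self, other):
        assert isinstance(other, Tensor)
        out = _node(np.matmul(self.data, other.data), (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    self._accum_owned(
                        np.ascontiguousarray(_unbroadcast(ga, self.data.shape)))
                if other.requires_grad:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accum_owned(
                        np.ascontiguousarray(_unbroadcast(gb, other.data.shape)))
            out._backward = bw
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = _node(y, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(y, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0))).astype(np.float32)
        out = _node(x * cdf, (self,))
        if out.requires_grad:
            pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
            out._backward = lambda g: self._accum(g * (cdf + x * pdf))
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).astype(np.float32))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims=False):
        m = self.data.max(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(m, axis=axis)
        out = _node(out_data, (self,))
        if out.requires_grad:
            mask = (self.data == m)
            cnt = mask.sum(axis=axis, keepdims=True)
            def bw(g):
                if not keepdims:
                    g = np.expand_dims(g, axis if isinstance(axis, int) else axis)
                self._accum(mask * (g / cnt))
            out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _node(np.ascontiguousarray(self.data.transpose(axes)), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(tuple(inv)))
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        if out.requires_grad:
            parts = idx if isinstance(idx, tuple) else (idx,)
            basic = all(isinstance(p, (slice, int)) or p is None or p is Ellipsis
                        for p in parts)
            def bw(g):
                buf = np.zeros_like(self.data)
                if basic:
                    buf[idx] = g
                else:   # fancy indexing may repeat entries: accumulate
                    np.add.at(buf, idx, g)
                self._accum_owned(buf)
            out._backward = bw
        return out

    def pad(self, pad_width, value: float = 0.0):
        """Constant-pad; `pad_width` as for np.pad."""
        out = _node(np.pad(self.data, pad_width, constant_values=value), (self,))
        if out.requires_grad:
            sl = tuple(slice(lo, lo + n) for (lo, _), n in zip(pad_width, self.data.shape))
            out._backward = lambda g: self._accum(g[sl])
        return out

    def roll(self, shift, axis):
        out = _node(np.roll(self.data, shift, axis=axis), (self,))
        if out.requires_grad:
            neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift
            out._backward = lambda g: self._accum(np.roll(g, neg, axis=axis))
        return out


def _node(data: np.ndarray, parents) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = np.asarray(data, dtype=np.float32)
    out.grad = None
    out._backward = None
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
    else:
        out.requires_grad = False
        out._parents = ()
    return out


# -- fused / structural functions ------------------------------------------

def concat(tensors, axis: int) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = _node(data, tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offs = np.cumsum([0] + sizes)
        def bw(g):
            for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=axis, keepdims=True)
    y = z
    out = _node(y, (x,))
    if out.requires_grad:
        def bw(g):
            gy = g * y
            s = gy.sum(axis=axis, keepdims=True)
            gy -= y * s
            x._accum_owned(gy)
        out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then scale/shift by (gamma, beta)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = _node(gamma.data * xhat + beta.data, (x, gamma, beta))
    if out.requires_grad:
        def bw(g):
            if gamma.requires_grad:
                gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
            if beta.requires_grad:
                beta._accum(_unbroadcast(g, beta.data.shape))
            if x.requires_grad:
                dxh = g * gamma.data
                m1 = dxh.mean(axis=-1, keepdims=True)
                m2 = (dxh * xhat).mean(axis=-1, keepdims=True)
                dxh -= m1
                dxh -= xhat * m2
                dxh *= inv
                x._accum_owned(dxh)
        out._backward = bw
    return out


def _triplet(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v, v)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, padding=0) -> Tensor:
    """3D convolution, layout (B, Cin, X, Y, Z); w: (Cout, Cin, k0, k1, k2)."""
    s0, s1, s2 = _triplet(stride)
    p0, p1, p2 = _triplet(padding)
    cout, cin, k0, k1, k2 = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (p0, p0), (p1, p1), (p2, p2)))
    o0 = (xp.shape[2] - k0) // s0 + 1
    o1 = (xp.shape[3] - k1) // s1 + 1
    o2 = (xp.shape[4] - k2) // s2 + 1
    out_data = np.zeros((x.data.shape[0], cout, o0, o1, o2), dtype=np.float32)
    for i in range(k0):
        for j in range(k1):
            for k in range(k2):
                xs = xp[:, :, i:i + o0 * s0:s0, j:j + o1 * s1:s1, k:k + o2 * s2:s2]
                out_data += np.einsum("bcxyz,dc->bdxyz", xs, w.data[:, :, i, j, k],
                                      optimize=True)
    parents = (x, w) if b is None else (x, w, b)
    if b is not None:
        out_data += b.data.reshape(1, cout, 1, 1, 1)
    out = _node(out_data, parents)
    if out.requires_grad:
        def bw(g):
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3, 4)))
            gxp = np.zeros_like(xp) if x.requires_grad else None
            for i in range(k0):
                for j in range(k1):
                    for k in range(k2):
                        xs = xp[:, :, i:i + o0 * s0:s0, j:j + o1 * s1:s1,
                                k:k + o2 * s2:s2]
                        if w.requires_grad:
                            gw = np.einsum("bcxyz,bdxyz->dc", xs, g, optimize=True)
                            if w.grad is None:
                                w.grad = np.zeros_like(w.data)
                            w.grad[:, :, i, j, k] += gw
                        if gxp is not None:
                            gxp[:, :, i:i + o0 * s0:s0, j:j + o1 * s1:s1,
                                k:k + o2 * s2:s2] += np.einsum(
                                "bdxyz,dc->bcxyz", g, w.data[:, :, i, j, k],
                                optimize=True)
            if gxp is not None:
                if (p0, p1, p2) == (0, 0, 0):
                    x._accum_owned(gxp)
                else:
                    sl = (slice(None), slice(None),
                          slice(p0, gxp.shape[2] - p0),
                          slice(p1, gxp.shape[3] - p1),
                          slice(p2, gxp.shape[4] - p2))
                    x._accum(gxp[sl])
        out._backward = bw
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride=1, padding=0) -> Tensor:
    """Transposed 3D convolution; w: (Cin, Cout, k0, k1, k2).

    Output extent per axis is ``(in - 1) * stride + k - 2 * padding``
    (the padding crops the border, mirroring the forward-conv convention).
    """
    pad = _triplet(padding)
    if any(pad):
        full = conv_transpose3d(x, w, b, stride, 0)
        sl = (slice(None), slice(None)) + tuple(
            slice(p, full.shape[2 + a] - p) for a, p in enumerate(pad))
        return full[sl]
    s0, s1, s2 = _triplet(stride)
    cin, cout, k0, k1, k2 = w.data.shape
    bsz, _, i0, i1, i2 = x.data.shape
    o0 = (i0 - 1) * s0 + k0
    o1 = (i1 - 1) * s1 + k1
    o2 = (i2 - 1) * s2 + k2
    out_data = np.zeros((bsz, cout, o0, o1, o2), dtype=np.float32)
    for i in range(k0):
        for j in range(k1):
            for k in range(k2):
                out_data[:, :, i:i + i0 * s0:s0, j:j + i1 * s1:s1,
                         k:k + i2 * s2:s2] += np.einsum(
                    "bcxyz,cd->bdxyz", x.data, w.data[:, :, i, j, k], optimize=True)
    if b is not None:
        out_data += b.data.reshape(1, cout, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = _node(out_data, parents)
    if out.requires_grad:
        def bw(g):
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3, 4)))
            gx = np.zeros_like(x.data) if x.requires_grad else None
            for i in range(k0):
                for j in range(k1):
                    for k in range(k2):
                        gs = g[:, :, i:i + i0 * s0:s0, j:j + i1 * s1:s1,
                               k:k + i2 * s2:s2]
                        if gx is not None:
                            gx += np.einsum("bdxyz,cd->bcxyz", gs,
                                            w.data[:, :, i, j, k], optimize=True)
                        if w.requires_grad:
                            gw = np.einsum("bcxyz,bdxyz->cd", x.data, gs,
                                           optimize=True)
                            if w.grad is None:
                                w.grad = np.zeros_like(w.data)
                            w.grad[:, :, i, j, k] += gw
            if gx is not None:
                x._accum_owned(gx)
        out._backward = bw
    return out
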