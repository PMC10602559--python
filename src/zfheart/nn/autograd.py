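"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is a deliberately small tensor engine — just the operations needed to
build and train the segmentation and heart-rate networks on CPU: broadcasted
arithmetic, matmul, (dilated) 2-D and 1-D convolution via im2col, max pooling,
nearest-neighbour upsampling, the usual pointwise nonlinearities and
reductions. Gradients are accumulated by topological-order backward passes;
correctness is property-tested against central finite differences.

All tensors are float32. The engine is single-threaded numpy and fully
deterministic: identical inputs and parameters give bit-identical outputs.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_DTYPE = np.float32

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode): ops build no backward
    closures, so intermediate results are freed by plain refcounting."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=_DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _register(out: "Tensor", fn) -> None:
    # the closure references `out`, which would form a reference cycle; only
    # attach it when a backward pass can actually need it (backward() then
    # breaks the cycle as it consumes the graph)
    if out.requires_grad:
        out._backward = fn


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        if not _GRAD_ENABLED:
            _prev = ()
            requires_grad = False
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev if self.requires_grad else ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g

    # ----- graph traversal -----
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def build(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        build(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward()
            # consume the graph: break closure cycles and free intermediate
            # grads so memory is reclaimed by refcounting, not the gc
            is_leaf = not t._prev
            t._backward = None
            t._prev = ()
            if not is_leaf and t is not self:
                t.grad = None

    # ----- arithmetic -----
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        _register(out, _bw)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        _register(out, _bw)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * Tensor(-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other.pow(-1.0)

    def pow(self, p: float):
        out = Tensor(np.power(self.data, p), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * p * np.power(self.data, p - 1.0))

        _register(out, _bw)
        return out

    def matmul(self, other: "Tensor"):
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accum(_unbroadcast(g, other.shape))

        _register(out, _bw)
        return out

    __matmul__ = matmul

    # ----- nonlinearities -----
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        _register(out, _bw)
        return out

    def sigmoid(self):
        d = self.data
        s = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))),
                     np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))
        out = Tensor(s, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        _register(out, _bw)
        return out

    def softplus(self):
        # numerically stable log(1 + e^x)
        d = self.data
        sp = np.where(d > 20, d, np.log1p(np.exp(np.minimum(d, 20))))
        out = Tensor(sp, _prev=(self,))

        def _bw():
            if self.requires_grad:
                e = np.exp(-np.abs(d))
                sig = np.where(d >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
                self._accum(out.grad * sig)

        _register(out, _bw)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        _register(out, _bw)
        return out

    # ----- reductions / reshaping -----
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).astype(_DTYPE))

        _register(out, _bw)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * Tensor(1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        _register(out, _bw)
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    _register(out, _bw)
    return out


# --------------------------------------------------------------------------
# Convolution (stride 1, 'same' padding, odd kernels, optional dilation)
# --------------------------------------------------------------------------

def _im2col2d(xp: np.ndarray, kh: int, kw: int, d: int, H: int, W: int):
    N, C = xp.shape[:2]
    cols = np.empty((N, C, kh, kw, H, W), dtype=_DTYPE)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i * d:i * d + H, j * d:j * d + W]
    return cols.reshape(N, C * kh * kw, H * W)


def conv2d(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """Same-size 2-D convolution. x: (N,C,H,W); w: (O,C,kh,kw); b: (O,)."""
    N, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    assert C == Cw and kh % 2 == 1 and kw % 2 == 1
    d = dilation
    ph, pw = d * (kh - 1) // 2, d * (kw - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = _im2col2d(xp, kh, kw, d, H, W)                       # (N, K, HW)
    w2 = w.data.reshape(O, -1)                                   # (O, K)
    y = np.matmul(w2, cols)                                      # (N, O, HW)
    y = y.reshape(N, O, H, W) + b.data.reshape(1, O, 1, 1)
    out = Tensor(y, _prev=(x, w, b))

    def _bw():
        dout = out.grad.reshape(N, O, H * W)
        if b.requires_grad:
            b._accum(out.grad.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.einsum("nop,nkp->ok", dout, cols, optimize=True)
            w._accum(dw.reshape(w.shape))
        if x.requires_grad:
            dcols = np.matmul(w2.T, dout)                        # (N, K, HW)
            dcols = dcols.reshape(N, C, kh, kw, H, W)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i * d:i * d + H, j * d:j * d + W] += dcols[:, :, i, j]
            x._accum(dxp[:, :, ph:ph + H, pw:pw + W] if ph or pw else dxp)

    _register(out, _bw)
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """Same-size 1-D convolution. x: (N,C,L); w: (O,C,k); b: (O,)."""
    N, C, L = x.shape
    O, Cw, k = w.shape
    assert C == Cw and k % 2 == 1
    d = dilation
    p = d * (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    cols = np.empty((N, C, k, L), dtype=_DTYPE)
    for i in range(k):
        cols[:, :, i] = xp[:, :, i * d:i * d + L]
    cols = cols.reshape(N, C * k, L)
    w2 = w.data.reshape(O, -1)
    y = np.matmul(w2, cols) + b.data.reshape(1, O, 1)
    out = Tensor(y, _prev=(x, w, b))

    def _bw():
        dout = out.grad
        if b.requires_grad:
            b._accum(dout.sum(axis=(0, 2)))
        if w.requires_grad:
            dw = np.einsum("nol,nkl->ok", dout, cols, optimize=True)
            w._accum(dw.reshape(w.shape))
        if x.requires_grad:
            dcols = np.matmul(w2.T, dout).reshape(N, C, k, L)
            dxp = np.zeros_like(xp)
            for i in range(k):
                dxp[:, :, i * d:i * d + L] += dcols[:, :, i]
            x._accum(dxp[:, :, p:p + L] if p else dxp)

    _register(out, _bw)
    return out


# --------------------------------------------------------------------------
# Pooling / upsampling (factor-2, even sizes)
# --------------------------------------------------------------------------

def maxpool2d(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    assert H % 2 == 0 and W % 2 == 0, "maxpool2d needs even spatial dims"
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(N, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0],
                 _prev=(x,))

    def _bw():
        if x.requires_grad:
            dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=_DTYPE)
            np.put_along_axis(dxr, idx[..., None], out.grad[..., None], axis=-1)
            dx = dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accum(dx.reshape(N, C, H, W))

    _register(out, _bw)
    return out


def maxpool1d(x: Tensor) -> Tensor:
    N, C, L = x.shape
    assert L % 2 == 0, "maxpool1d needs even length"
    xr = x.data.reshape(N, C, L // 2, 2)
    idx = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0],
                 _prev=(x,))

    def _bw():
        if x.requires_grad:
            dxr = np.zeros_like(xr)
            np.put_along_axis(dxr, idx[..., None], out.grad[..., None], axis=-1)
            x._accum(dxr.reshape(N, C, L))

    _register(out, _bw)
    return out


def upsample2d(x: Tensor) -> Tensor:
    """Nearest-neighbour factor-2 upsampling."""
    N, C, H, W = x.shape
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), _prev=(x,))

    def _bw():
        if x.requires_grad:
            g = out.grad.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5))
            x._accum(g)

    _register(out, _bw)
    return out


def global_avgpool2d(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C,1,1)."""
    return x.mean(axis=(2, 3), keepdims=True)
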