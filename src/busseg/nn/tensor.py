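"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based autodiff engine providing exactly the operations the
segmentation network needs: broadcasting arithmetic, batched matmul,
pointwise nonlinearities, reductions, shape ops, zero padding, softmax,
2-D convolution (dense and depthwise, via strided im2col), bilinear /
nearest resampling and dropout.  Gradients flow through a dynamically
built graph; ``Tensor.backward()`` runs a topological sweep.

Arrays keep whatever float dtype they are given (float32 by default for
parameters), so finite-difference gradient checks can run in float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _as_array(x, like=None):
    if isinstance(x, np.ndarray):
        return x
    if isinstance(x, np.generic):  # 0-d reduction results keep their dtype
        return np.asarray(x)
    dtype = like.dtype if like is not None else np.float32
    return np.asarray(x, dtype=dtype)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (evaluation paths)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "_retain")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()
        self._retain = requires_grad

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def retain_grad(self) -> "Tensor":
        self._retain = True
        return self

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------- graph glue
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g, own: bool = False):
        """Accumulate a gradient; ``own=True`` means `g` is freshly
        allocated by the caller and may be adopted without copying."""
        if self.grad is None:
            if own and g.dtype == self.data.dtype:
                self.grad = g
            else:
                self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._prev:
                    stack.append((p, False))

        visit(self)
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
            # release the graph and interior grads as the sweep passes, so
            # peak memory is bounded by the live frontier, not the whole tape
            node._backward = None
            node._prev = ()
            if not node._retain:
                node.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape), own=True)

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape), own=True)

        return Tensor._make(data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(_as_array(other, self.data)) / self

    def __pow__(self, p: float):
        data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1), own=True)

        return Tensor._make(data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape), own=True)
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape), own=True)

        return Tensor._make(data, (self, other), backward)

    # ------------------------------------------------------------- pointwise
    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * data, own=True)

        return Tensor._make(data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data, own=True)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / data, own=True)

        return Tensor._make(data, (self,), backward)

    def tanh(self):
        data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - data**2), own=True)

        return Tensor._make(data, (self,), backward)

    def sigmoid(self):
        x = self.data
        data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def backward(g):
            if self.requires_grad:
                self._accum(g * data * (1.0 - data), own=True)

        return Tensor._make(data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask, own=True)

        return Tensor._make(data, (self,), backward)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        data = self.data * s

        def backward(g):
            if self.requires_grad:
                self._accum(g * (s + self.data * s * (1.0 - s)), own=True)

        return Tensor._make(data, (self,), backward)

    def softplus(self):
        # log(1 + e^x), numerically stable
        x = self.data
        data = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s, own=True)

        return Tensor._make(data, (self,), backward)

    def clamp(self, lo=None, hi=None):
        data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data)
        if lo is not None:
            mask = mask * (self.data >= lo)
        if hi is not None:
            mask = mask * (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask, own=True)

        return Tensor._make(data, (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy(), own=True)
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.data.ndim for a in axes)
                shape = tuple(1 if i in axes else s for i, s in enumerate(self.data.shape))
                g = g.reshape(shape)
            self._accum(np.broadcast_to(g, self.data.shape).copy(), own=True)

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a % self.data.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(data, (self,), backward)

    def flip(self, axis):
        data = np.flip(self.data, axis=axis)

        def backward(g):
            if self.requires_grad:
                self._accum(np.flip(g, axis=axis))

        return Tensor._make(data, (self,), backward)

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(data, (self,), backward)

    def pad2d(self, ph: int, pw: int):
        """Zero-pad the last two axes by (ph, pw) on both sides."""
        if ph == 0 and pw == 0:
            return self
        pads = [(0, 0)] * (self.data.ndim - 2) + [(ph, ph), (pw, pw)]
        data = np.pad(self.data, pads)
        sl = tuple([slice(None)] * (self.data.ndim - 2) + [slice(ph, data.shape[-2] - ph), slice(pw, data.shape[-1] - pw)])

        def backward(g):
            if self.requires_grad:
                self._accum(g[sl])

        return Tensor._make(data, (self,), backward)


def concat(tensors, axis=0):
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), backward)


def stack(tensors, axis=0):
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(data, tuple(tensors), backward)


def where(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)
    data = np.where(cond, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(np.where(cond, g, 0.0), a.data.shape), own=True)
        if b.requires_grad:
            b._accum(_unbroadcast(np.where(cond, 0.0, g), b.data.shape), own=True)

    return Tensor._make(data, (a, b), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * data).sum(axis=axis, keepdims=True)
            x._accum(data * (g - dot), own=True)

    return Tensor._make(data, (x,), backward)


# ---------------------------------------------------------------- convolution
def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), x:(B,C,H,W), w:(Co,C,kh,kw)."""
    B, C, H, W = x.data.shape
    Co, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (xp.shape[2] - kh) // stride + 1
    Wo = (xp.shape[3] - kw) // stride + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B, Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(Co, -1)
    out = cols @ wmat.T  # (B, HoWo, Co)
    if b is not None:
        out = out + b.data
    data = out.transpose(0, 2, 1).reshape(B, Co, Ho, Wo)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.reshape(B, Co, Ho * Wo).transpose(0, 2, 1)  # (B,HoWo,Co)
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = np.einsum("bpo,bpk->ok", gmat, cols, optimize=True)
            w._accum(np.ascontiguousarray(gw.reshape(w.data.shape)), own=True)
        if x.requires_grad:
            dcols = gmat @ wmat  # (B,HoWo,C*kh*kw)
            dcols = dcols.reshape(B, Ho, Wo, C, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += dcols[
                        :, :, :, :, i, j
                    ].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp, own=True)

    return Tensor._make(data, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """Per-channel 2-D convolution, x:(B,C,H,W), w:(C,kh,kw), stride 1."""
    B, C, H, W = x.data.shape
    Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError("depthwise_conv2d channel mismatch")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = xp.shape[2] - kh + 1
    Wo = xp.shape[3] - kw + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (B,C,Ho,Wo,kh,kw)
    data = np.einsum("bchwij,cij->bchw", win, w.data, optimize=True)
    if b is not None:
        data = data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum(np.einsum("bchw,bchwij->cij", g, win, optimize=True))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + Ho, j : j + Wo] += g * w.data[None, :, i, j, None, None]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp, own=True)

    return Tensor._make(data, parents, backward)


# --------------------------------------------------------------- resampling
def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    data = x.data.repeat(factor, axis=-2).repeat(factor, axis=-1)

    def backward(g):
        if x.requires_grad:
            B = g.shape[:-2]
            H, W = x.data.shape[-2:]
            gg = g.reshape(*B, H, factor, W, factor).sum(axis=(-3, -1))
            x._accum(gg)

    return Tensor._make(data, (x,), backward)


def _bilinear_weights(h_in, w_in, h_out, w_out):
    """Half-pixel-centre bilinear sampling indices and weights."""

    def axis(n_in, n_out):
        pos = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        lo = np.floor(pos).astype(int)
        frac = pos - lo
        lo0 = np.clip(lo, 0, n_in - 1)
        lo1 = np.clip(lo + 1, 0, n_in - 1)
        return lo0, lo1, frac

    r0, r1, fr = axis(h_in, h_out)
    c0, c1, fc = axis(w_in, w_out)
    return r0, r1, fr, c0, c1, fc


_BILINEAR_CACHE: dict = {}


def _bilinear_matrix(h_in, w_in, h_out, w_out):
    """Sparse (h_out*w_out, h_in*w_in) bilinear interpolation operator."""
    from scipy import sparse

    key = (h_in, w_in, h_out, w_out)
    M = _BILINEAR_CACHE.get(key)
    if M is None:
        r0, r1, fr, c0, c1, fc = _bilinear_weights(h_in, w_in, h_out, w_out)
        rows = np.repeat(np.arange(h_out * w_out), 4)
        RR0 = np.repeat(r0, w_out)
        RR1 = np.repeat(r1, w_out)
        CC0 = np.tile(c0, h_out)
        CC1 = np.tile(c1, h_out)
        FR = np.repeat(fr, w_out)
        FC = np.tile(fc, h_out)
        cols = np.stack([RR0 * w_in + CC0, RR0 * w_in + CC1, RR1 * w_in + CC0, RR1 * w_in + CC1], axis=1).ravel()
        vals = np.stack(
            [(1 - FR) * (1 - FC), (1 - FR) * FC, FR * (1 - FC), FR * FC], axis=1
        ).ravel()
        M = sparse.csr_matrix((vals, (rows, cols)), shape=(h_out * w_out, h_in * w_in))
        _BILINEAR_CACHE[key] = M
    return M


def upsample_bilinear(x: Tensor, h_out: int, w_out: int) -> Tensor:
    """Bilinear resize of the last two axes (half-pixel centers)."""
    H, W = x.data.shape[-2:]
    lead = x.data.shape[:-2]
    M = _bilinear_matrix(H, W, h_out, w_out)
    flat = x.data.reshape(-1, H * W)
    data = (M @ flat.T).T.reshape(*lead, h_out, w_out)

    def backward(g):
        if x.requires_grad:
            gf = g.reshape(-1, h_out * w_out)
            gx = (M.T @ gf.T).T.reshape(x.data.shape)
            x._accum(np.ascontiguousarray(gx), own=True)

    return Tensor._make(data.astype(x.data.dtype, copy=False), (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    mask = mask.astype(x.data.dtype)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)
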