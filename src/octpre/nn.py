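"""Minimal tape-based autodiff engine for the segmentation networks.

Everything operates on float32 ``(N, C, H, W)`` arrays.  Only the ops the
encoder--decoder architectures need are provided: stride-1 same-padded
(optionally dilated) convolution, 2x2 max-pool with stored indices, 2x2
unpool / up-convolution, batch normalisation, ReLU/sigmoid, channel concat,
broadcast multiply, reflection padding, channel softmax, and an Adam
optimizer.  Convolutions are evaluated with sliding-window views and
``tensordot`` so a full forward/backward pass stays inside BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam"]

_F32 = np.float32


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=_F32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    def backward(self, grad):
        """Back-propagate ``grad`` (dL/dself) through the tape."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=_F32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # free the tape but keep data (used between training steps)
    def detach(self):
        return Tensor(self.data)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self):
        self.grad = None


# ---------------------------------------------------------------------------
# convolution


def _windows(xp, kh, kw, dilation):
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (eh, ew), axis=(2, 3))
    if dilation > 1:
        win = win[..., ::dilation, ::dilation]
    return win


def _conv2d_raw(x, w, dilation):
    # x: (N,C,H,W), w: (O,C,kh,kw) -> (N,O,H,W), stride 1, same padding
    kh, kw = w.shape[2], w.shape[3]
    ph = (kh - 1) // 2 * dilation
    pw = (kw - 1) // 2 * dilation
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = _windows(xp, kh, kw, dilation)
    out = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,O)
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2)), xp


def conv2d(x: Tensor, w: Parameter, b: Parameter, dilation: int = 1) -> Tensor:
    """Same-padded stride-1 convolution with odd kernel dims."""
    kh, kw = w.data.shape[2], w.data.shape[3]
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel dims must be odd for same padding")
    out_data, xp = _conv2d_raw(x.data, w.data, dilation)
    out_data += b.data[None, :, None, None]

    def backward(g):
        if w.requires_grad:
            win = _windows(xp, kh, kw, dilation)
            dw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))
            w._accumulate(dw)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            dx, _ = _conv2d_raw(g, np.ascontiguousarray(w_flip), dilation)
            x._accumulate(dx)

    return Tensor(out_data, (x, w, b), backward)


def conv_transpose2x2(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """2x2 stride-2 transposed convolution (the UNet up-conv).

    ``w`` has shape (C_in, C_out, 2, 2); output is (N, C_out, 2H, 2W).
    """
    n, c, h, wd = x.data.shape
    co = w.data.shape[1]
    out = np.einsum("nchw,coij->nohiwj", x.data, w.data, optimize=True)
    out = out.reshape(n, co, 2 * h, 2 * wd) + b.data[None, :, None, None]

    def backward(g):
        g6 = g.reshape(n, co, h, 2, wd, 2)
        if w.requires_grad:
            dw = np.einsum("nchw,nohiwj->coij", x.data, g6, optimize=True)
            w._accumulate(dw)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dx = np.einsum("nohiwj,coij->nchw", g6, w.data, optimize=True)
            x._accumulate(dx)

    return Tensor(out, (x, w, b), backward)


# ---------------------------------------------------------------------------
# pooling


def maxpool2x2(x: Tensor):
    """2x2 stride-2 max pool.  Returns (pooled Tensor, indices array)."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = np.ascontiguousarray(v).reshape(n, c, h // 2, w // 2, 4)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            dv = np.zeros((n, c, h // 2, w // 2, 4), dtype=_F32)
            np.put_along_axis(dv, idx[..., None], g[..., None], axis=-1)
            dx = dv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(np.ascontiguousarray(dx).reshape(n, c, h, w))

    return Tensor(out, (x,), backward), idx


def maxunpool2x2(x: Tensor, idx) -> Tensor:
    """Inverse of :func:`maxpool2x2` using the stored argmax indices."""
    n, c, h, w = x.data.shape
    v = np.zeros((n, c, h, w, 4), dtype=_F32)
    np.put_along_axis(v, idx[..., None], x.data[..., None], axis=-1)
    out = v.reshape(n, c, h, w, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    out = np.ascontiguousarray(out).reshape(n, c, 2 * h, 2 * w)

    def backward(g):
        if x.requires_grad:
            gv = g.reshape(n, c, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)
            gv = np.ascontiguousarray(gv).reshape(n, c, h, w, 4)
            x._accumulate(np.take_along_axis(gv, idx[..., None], axis=-1)[..., 0])

    return Tensor(out, (x,), backward)


# ---------------------------------------------------------------------------
# pointwise / structural ops


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable form: never exponentiates a positive argument
    z = np.exp(-np.abs(x.data))
    out = np.where(x.data >= 0, 1.0 / (1.0 + z), z / (1.0 + z)).astype(_F32)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out * (1.0 - out))

    return Tensor(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return Tensor(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise multiply with broadcasting (attention gating)."""
    out = a.data * b.data

    def _reduce(g, shape):
        extra = g.ndim - len(shape)
        if extra:
            g = g.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] > 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        return g

    def backward(g):
        if a.requires_grad:
            a._accumulate(_reduce(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_reduce(g * a.data, b.data.shape))

    return Tensor(out, (a, b), backward)


def concat(tensors) -> Tensor:
    tensors = list(tensors)
    out = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]

    def backward(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                t._accumulate(g[:, start : start + s])
            start += s

    return Tensor(out, tuple(tensors), backward)


def pad_reflect(x: Tensor, pad) -> Tensor:
    """Reflection-pad the spatial dims; exact scatter-add backward.

    ``pad`` = (top, bottom, left, right).
    """
    t, b, l, r = pad
    if t == b == l == r == 0:
        return x
    n, c, h, w = x.data.shape
    iy = np.pad(np.arange(h), (t, b), mode="reflect")
    ix = np.pad(np.arange(w), (l, r), mode="reflect")
    out = x.data[:, :, iy[:, None], ix[None, :]]

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            np.add.at(dx, (slice(None), slice(None), iy[:, None], ix[None, :]), g)
            x._accumulate(dx)

    return Tensor(out, (x,), backward)


def crop(x: Tensor, h: int, w: int) -> Tensor:
    """Crop the spatial dims to the top-left (h, w) window."""
    out = x.data[:, :, :h, :w]

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            dx[:, :, :h, :w] = g
            x._accumulate(dx)

    return Tensor(np.ascontiguousarray(out), (x,), backward)


def batchnorm2d(x: Tensor, gamma: Parameter, beta: Parameter, state: dict,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W)."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        state["mean"] = (1 - momentum) * state["mean"] + momentum * mean
        state["var"] = (1 - momentum) * state["var"] + momentum * var
    else:
        mean, var = state["mean"], state["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = g * gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                s1 = gi.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gi * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (gi - s1 / m - xhat * s2 / m) * inv[None, :, None, None]
            else:
                dx = gi * inv[None, :, None, None]
            x._accumulate(dx.astype(_F32))

    return Tensor(out, (x, gamma, beta), backward)


def softmax_channels(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dx = out * (g - (g * out).sum(axis=1, keepdims=True))
            x._accumulate(dx)

    return Tensor(out, (x,), backward)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam over a list of :class:`Parameter`."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
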