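"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the package needs: elementwise
arithmetic, ReLU/Softplus/log/exp/abs/power, reductions, 2-D convolution
(im2col), 2x average pooling, bilinear resizing, and the fixed-kernel
full-range convolution used by the spatial filter.  Gradients are
accumulated by topological traversal of the recorded graph.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve

__all__ = ["Tensor", "conv2d", "avg_pool2", "bilinear_resize", "prior_message", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- graph plumbing -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, req, parents if req else (), backward if req else None)

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(g, self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- elementwise ----------------------------------------------------
    def __add__(self, other):
        o = self._lift(other)
        out = self._make(self.data + o.data, (self, o), None)
        out._backward = lambda g: (self._accum(g), o._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        o = self._lift(other)
        out = self._make(self.data * o.data, (self, o), None)
        out._backward = lambda g: (self._accum(g * o.data), o._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._lift(other)
        out = self._make(self.data / o.data, (self, o), None)
        out._backward = lambda g: (
            self._accum(g / o.data),
            o._accum(-g * self.data / (o.data**2)),
        )
        return out

    def pow_const(self, exponent) -> "Tensor":
        """x ** e with a constant (scalar or array) exponent; x >= 0 assumed
        where the exponent is non-integer."""
        e = np.asarray(exponent)
        out = self._make(self.data**e, (self,), None)

        def bw(g):
            base = np.where(self.data == 0.0, 0.0, self.data ** np.where(e == 0, 0, e - 1))
            self._accum(g * e * base)

        out._backward = bw
        return out

    def exp(self):
        val = np.exp(self.data)
        out = self._make(val, (self,), None)
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def abs(self):
        out = self._make(np.abs(self.data), (self,), None)
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)
        out._backward = lambda g: self._accum(g * mask)
        return out

    def softplus(self, beta: float = 1.0):
        """(1/beta) * ln(1 + exp(beta*x)), numerically stable."""
        z = beta * self.data
        val = (np.logaddexp(0.0, z)) / beta
        sig = 1.0 / (1.0 + np.exp(-z))
        out = self._make(val, (self,), None)
        out._backward = lambda g: self._accum(g * sig)
        return out

    # -- reductions & shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.data.shape
        out = self._make(self.data.reshape(*shape), (self,), None)
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def __getitem__(self, key):
        out = self._make(self.data[key], (self,), None)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        out._backward = bw
        return out


# -- structured operations ----------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: str = "same") -> Tensor:
    """2-D convolution (cross-correlation) of (N,C,H,W) with (O,C,kh,kw).

    'same' padding requires odd kernel sizes; 'valid' is unpadded.
    """
    kh, kw = w.data.shape[2:]
    if padding == "same":
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("'same' convolution requires odd kernel sizes")
        ph, pw = kh // 2, kw // 2
    elif padding == "valid":
        ph = pw = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if ph or pw else x.data
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,Ho,Wo,kh,kw)
    val = np.einsum("ncyxhw,ochw->noyx", win, w.data, optimize=True)
    if b is not None:
        val = val + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(val, any(p.requires_grad for p in parents), parents)

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("ncyxhw,noyx->ochw", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (kh - 1 - ph, kh - 1 - ph), (kw - 1 - pw, kw - 1 - pw)))
            gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
            wf = w.data[:, :, ::-1, ::-1]
            x._accum(np.einsum("noyxhw,ochw->ncyx", gwin, wf, optimize=True))

    out._backward = bw
    return out


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2; odd dims are edge-padded first."""
    n, c, h, w = x.data.shape
    ph, pw = h % 2, w % 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge") if ph or pw else x.data
    hp, wp = h + ph, w + pw
    val = xp.reshape(n, c, hp // 2, 2, wp // 2, 2).mean(axis=(3, 5))
    out = Tensor(val, x.requires_grad, (x,))

    def bw(g):
        gf = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        if ph:
            gf[:, :, h - 1, :] += gf[:, :, h, :]
            gf = gf[:, :, :h, :]
        if pw:
            gf[:, :, :, w - 1] += gf[:, :, :, w]
            gf = gf[:, :, :, :w]
        x._accum(gf)

    out._backward = bw
    return out


def _resize_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Bilinear interpolation matrix (n_out, n_in), pixel-center aligned."""
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m = np.zeros((n_out, n_in), dtype=dtype)
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinearly resize (N,C,H,W) to (N,C,*out_hw)."""
    n, c, h, w = x.data.shape
    ho, wo = out_hw
    a = _resize_matrix(h, ho, x.data.dtype)
    bmat = _resize_matrix(w, wo, x.data.dtype)
    val = np.einsum("oh,nchw,pw->ncop", a, x.data, bmat, optimize=True)
    out = Tensor(val, x.requires_grad, (x,))

    def bw(g):
        x._accum(np.einsum("oh,ncop,pw->nchw", a, g, bmat, optimize=True))

    out._backward = bw
    return out


def prior_message(x: Tensor, kernels: np.ndarray, pad_vals: np.ndarray,
                  anchor: tuple[int, int]) -> Tensor:
    """Full-range correlation of (B,H,W) maps with per-slice fixed kernels.

    For each batch slice b and output cell c:
        out[b, c] = sum_y K~[b, anchor + c - y] * x[b, y]
    where K~ equals ``kernels[b]`` inside its grid and ``pad_vals[b]``
    outside.  This is the anchored-shift semantics of the spatial filter;
    the kernel is as large as the map and the sum runs over every map cell.
    """
    bsz, h, w = x.data.shape
    a0, b0 = anchor
    q = kernels - pad_vals[:, None, None]
    full = fftconvolve(x.data, q, axes=(1, 2))  # (B, 2H-1, 2W-1)
    base = pad_vals[:, None, None] * x.data.sum(axis=(1, 2), keepdims=True)
    val = full[:, a0 : a0 + h, b0 : b0 + w] + base
    out = Tensor(val, x.requires_grad, (x,))

    def bw(g):
        gf = fftconvolve(g, q[:, ::-1, ::-1], axes=(1, 2))
        gx = gf[:, h - 1 - a0 : 2 * h - 1 - a0, w - 1 - b0 : 2 * w - 1 - b0]
        x._accum(gx + pad_vals[:, None, None] * g.sum(axis=(1, 2), keepdims=True))

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
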