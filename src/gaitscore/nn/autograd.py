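"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough tensor calculus for the three small scoring networks: elementwise
arithmetic with broadcasting, matmul, reshape/transpose/slice, reductions,
sigmoid/tanh/ReLU, softmax, fused softmax-cross-entropy, stride-1 valid
convolutions (1-D and 3-D, via sliding windows + einsum) and max-pooling.
Gradients are accumulated by topologically sorted backward passes; every op's
backward is verified against finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: Tuple["Tensor", ...] = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] = lambda: None
        self._prev = _prev

    # ---------------------------------------------------------------- infra
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for t in reversed(topo):
            t._backward()

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev, backward) -> "Tensor":
        req = any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=req, _prev=tuple(prev) if req else ())
        if req:
            out._backward = backward(out)
        return out

    # ----------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(out.grad, other.shape))
            return run

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad * other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(out.grad * self.data, other.shape))
            return run

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * (other ** -1.0)

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bw(out):
            def run():
                self._accum(out.grad * e * self.data ** (e - 1))
            return run

        return self._make(self.data ** e, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(out):
            def run():
                if self.requires_grad:
                    g = out.grad @ np.swapaxes(other.data, -1, -2)
                    self._accum(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    g = np.swapaxes(self.data, -1, -2) @ out.grad
                    other._accum(_unbroadcast(g, other.shape))
            return run

        return self._make(self.data @ other.data, (self, other), bw)

    # ------------------------------------------------------------ pointwise
    def exp(self):
        y = np.exp(self.data)

        def bw(out):
            def run():
                self._accum(out.grad * y)
            return run

        return self._make(y, (self,), bw)

    def log(self):
        def bw(out):
            def run():
                self._accum(out.grad / self.data)
            return run

        return self._make(np.log(self.data), (self,), bw)

    def tanh(self):
        y = np.tanh(self.data)

        def bw(out):
            def run():
                self._accum(out.grad * (1 - y ** 2))
            return run

        return self._make(y, (self,), bw)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))

        def bw(out):
            def run():
                self._accum(out.grad * y * (1 - y))
            return run

        return self._make(y, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(out):
            def run():
                self._accum(out.grad * mask)
            return run

        return self._make(self.data * mask, (self,), bw)

    # ------------------------------------------------------------- reshape
    def reshape(self, *shape):
        old = self.shape

        def bw(out):
            def run():
                self._accum(out.grad.reshape(old))
            return run

        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)

        def bw(out):
            def run():
                self._accum(out.grad.transpose(inv))
            return run

        return self._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key):
        def bw(out):
            def run():
                g = np.zeros_like(self.data)
                np.add.at(g, key, out.grad)
                self._accum(g)
            return run

        return self._make(self.data[key], (self,), bw)

    # ----------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def bw(out):
            def run():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())
            return run

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -------------------------------------------------------------- softmax
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def bw(out):
            def run():
                g = out.grad
                self._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))
            return run

        return self._make(y, (self,), bw)


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  class_weights: Optional[np.ndarray] = None) -> Tensor:
    """Mean weighted softmax cross-entropy; ``labels`` are integer classes."""
    labels = np.asarray(labels, dtype=int)
    n, k = logits.shape
    w = np.ones(k) if class_weights is None else np.asarray(class_weights, float)
    sw = w[labels]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1)) - z[np.arange(n), labels]
    loss_val = float((sw * lse).sum() / sw.sum())

    def bw(out):
        def run():
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(n), labels] -= 1.0
            logits._accum(out.grad * p * (sw / sw.sum())[:, None])
        return run

    req = logits.requires_grad
    out = Tensor(loss_val, requires_grad=req, _prev=(logits,) if req else ())
    if req:
        out._backward = bw(out)
    return out


# ------------------------------------------------------------- convolutions
# Implemented as sums over kernel offsets: each term is one strided slice
# times one weight plane, so peak memory stays at a single output-sized array.
def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid stride-1 1-D convolution: x (B,Cin,L), w (Cout,Cin,K) → (B,Cout,L')."""
    K = w.shape[2]
    Lp = x.shape[2] - K + 1
    y = np.tile(b.data[None, :, None], (x.shape[0], 1, Lp)).astype(float)
    for k in range(K):
        y += np.einsum("bcl,oc->bol", x.data[:, :, k:k + Lp], w.data[:, :, k])

    def bw(out):
        def run():
            g = out.grad
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2)))
            gx = np.zeros_like(x.data) if x.requires_grad else None
            for k in range(K):
                xs = x.data[:, :, k:k + Lp]
                if w.requires_grad:
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, k] += np.einsum("bcl,bol->oc", xs, g)
                if gx is not None:
                    gx[:, :, k:k + Lp] += np.einsum(
                        "bol,oc->bcl", g, w.data[:, :, k])
            if gx is not None:
                x._accum(gx)
        return run

    req = x.requires_grad or w.requires_grad or b.requires_grad
    out = Tensor(y, requires_grad=req, _prev=(x, w, b) if req else ())
    if req:
        out._backward = bw(out)
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid stride-1 3-D convolution: x (B,Cin,D,H,W), w (Cout,Cin,k1,k2,k3)."""
    k1, k2, k3 = w.shape[2:]
    D = x.shape[2] - k1 + 1
    H = x.shape[3] - k2 + 1
    W = x.shape[4] - k3 + 1
    offs = [(i, j, k) for i in range(k1) for j in range(k2) for k in range(k3)]
    y = np.tile(b.data[None, :, None, None, None],
                (x.shape[0], 1, D, H, W)).astype(float)
    for i, j, k in offs:
        y += np.einsum("bcdhw,oc->bodhw",
                       x.data[:, :, i:i + D, j:j + H, k:k + W],
                       w.data[:, :, i, j, k])

    def bw(out):
        def run():
            g = out.grad
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3, 4)))
            gx = np.zeros_like(x.data) if x.requires_grad else None
            for i, j, k in offs:
                xs = x.data[:, :, i:i + D, j:j + H, k:k + W]
                if w.requires_grad:
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, i, j, k] += np.einsum("bcdhw,bodhw->oc", xs, g)
                if gx is not None:
                    gx[:, :, i:i + D, j:j + H, k:k + W] += np.einsum(
                        "bodhw,oc->bcdhw", g, w.data[:, :, i, j, k])
            if gx is not None:
                x._accum(gx)
        return run

    req = x.requires_grad or w.requires_grad or b.requires_grad
    out = Tensor(y, requires_grad=req, _prev=(x, w, b) if req else ())
    if req:
        out._backward = bw(out)
    return out


def _pool_reshape(data: np.ndarray, ks: Sequence[int]) -> np.ndarray:
    """Crop trailing remainder and expose pooling windows as extra axes."""
    b, c = data.shape[:2]
    spatial = data.shape[2:]
    crop = [s - s % k for s, k in zip(spatial, ks)]
    sl = (slice(None), slice(None)) + tuple(slice(0, cr) for cr in crop)
    data = data[sl]
    newshape: List[int] = [b, c]
    for cr, k in zip(crop, ks):
        newshape += [cr // k, k]
    return data.reshape(newshape)


def max_pool(x: Tensor, ks: Sequence[int]) -> Tensor:
    """Non-overlapping max pooling over the trailing spatial axes."""
    ks = tuple(int(k) for k in ks)
    r = _pool_reshape(x.data, ks)
    win_axes = tuple(3 + 2 * i for i in range(len(ks)))
    y = r.max(axis=win_axes)

    def bw(out):
        def run():
            yexp = np.expand_dims(y, win_axes)
            mask = (r == yexp)
            cnt = mask.sum(axis=win_axes, keepdims=True)
            gexp = np.expand_dims(out.grad, win_axes)
            gr = mask * gexp / cnt
            g = np.zeros_like(x.data)
            sl = (slice(None), slice(None)) + tuple(
                slice(0, (s - s % k)) for s, k in zip(x.data.shape[2:], ks))
            g[sl] = gr.reshape(g[sl].shape)
            x._accum(g)
        return run

    req = x.requires_grad
    out = Tensor(y, requires_grad=req, _prev=(x,) if req else ())
    if req:
        out._backward = bw(out)
    return out


def avg_pool(x: Tensor, ks: Sequence[int]) -> Tensor:
    """Non-overlapping average pooling over the trailing spatial axes."""
    ks = tuple(int(k) for k in ks)
    r = _pool_reshape(x.data, ks)
    win_axes = tuple(3 + 2 * i for i in range(len(ks)))
    y = r.mean(axis=win_axes)
    scale = 1.0 / float(np.prod(ks))

    def bw(out):
        def run():
            gexp = np.broadcast_to(np.expand_dims(out.grad, win_axes), r.shape)
            g = np.zeros_like(x.data)
            sl = (slice(None), slice(None)) + tuple(
                slice(0, (s - s % k)) for s, k in zip(x.data.shape[2:], ks))
            g[sl] = (gexp * scale).reshape(g[sl].shape)
            x._accum(g)
        return run

    req = x.requires_grad
    out = Tensor(y, requires_grad=req, _prev=(x,) if req else ())
    if req:
        out._backward = bw(out)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    y = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(out):
        def run():
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * y.ndim
                    sl[axis] = slice(a, b)
                    t._accum(out.grad[tuple(sl)])
        return run

    req = any(t.requires_grad for t in tensors)
    out = Tensor(y, requires_grad=req, _prev=tuple(tensors) if req else ())
    if req:
        out._backward = bw(out)
    return out
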