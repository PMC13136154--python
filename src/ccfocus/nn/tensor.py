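"""Minimal reverse-mode autodiff over numpy arrays.

Supports exactly the operations the dual-stream classifier needs:
elementwise add/mul (with broadcasting), matmul, 2-D convolution,
ReLU/sigmoid, global average pooling, concatenation, masked sums and a
fused weighted softmax cross-entropy. Gradients of intermediate
activations can be retained, which is what the Grad-CAM++ code relies on.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes numpy prepended
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "retains_grad",
                 "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self.retains_grad = False
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def retain_grad(self):
        self.retains_grad = True
        return self

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order
        order, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=DTYPE)}
        for t in reversed(order):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.retains_grad or not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for p, pg in t._backward(g):
                    if not p.requires_grad:
                        continue
                    key = id(p)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    def zero_grad(self):
        self.grad = None

    # -- convenience operators --------------------------------------------
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- primitive ops ---------------------------------------------------------

def add(a, b):
    if not isinstance(b, Tensor):  # constant
        data = a.data + np.asarray(b, dtype=DTYPE)
        return _node(data, (a,), lambda g: [(a, _unbroadcast(g, a.shape))])
    data = a.data + b.data
    return _node(data, (a, b), lambda g: [(a, _unbroadcast(g, a.shape)),
                                          (b, _unbroadcast(g, b.shape))])


def mul(a, b):
    if not isinstance(b, Tensor):  # constant (ndarray or scalar)
        c = np.asarray(b, dtype=DTYPE)
        data = a.data * c
        return _node(data, (a,), lambda g: [(a, _unbroadcast(g * c, a.shape))])
    data = a.data * b.data
    return _node(data, (a, b),
                 lambda g: [(a, _unbroadcast(g * b.data, a.shape)),
                            (b, _unbroadcast(g * a.data, b.shape))])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data
    return _node(data, (a, b),
                 lambda g: [(a, g @ b.data.T), (b, a.data.T @ g)])


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return _node(a.data * mask, (a,), lambda g: [(a, g * mask)])


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    return _node(s, (a,), lambda g: [(a, g * s * (1.0 - s))])


def gap(a: Tensor) -> Tensor:
    """Global average pooling over the two trailing spatial axes: (N,C,H,W) -> (N,C)."""
    n, c, h, w = a.data.shape
    data = a.data.mean(axis=(2, 3))

    def backward(g):
        return [(a, np.broadcast_to(g[:, :, None, None] / (h * w), a.data.shape).copy())]

    return _node(data, (a,), backward)


def concat(tensors, axis=1):
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        out, start = [], 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            out.append((t, g[tuple(sl)]))
            start += s
        return out

    return _node(data, tuple(tensors), backward)


def tsum(a: Tensor) -> Tensor:
    data = np.asarray(a.data.sum())
    return _node(data, (a,), lambda g: [(a, np.broadcast_to(g, a.data.shape).astype(DTYPE).copy())])


# -- convolution -----------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    sn, sc, sh, sw = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, ho, wo), (sn, sc, sh, sw, sh * stride, sw * stride))
    return view.reshape(n, c * kh * kw, ho * wo), (ho, wo)


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad, ho, wo):
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           pad: int = 1) -> Tensor:
    n = x.data.shape[0]
    o, c, kh, kw = weight.data.shape
    cols, (ho, wo) = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(o, -1)
    out = np.einsum("ok,nkp->nop", wmat, cols, optimize=True)
    if bias is not None:
        out += bias.data[None, :, None]
    data = out.reshape(n, o, ho, wo)

    def backward(g):
        gf = g.reshape(n, o, ho * wo)
        grads = []
        if weight.requires_grad:
            gw = np.einsum("nop,nkp->ok", gf, cols, optimize=True).reshape(weight.data.shape)
            grads.append((weight, gw))
        if bias is not None and bias.requires_grad:
            grads.append((bias, gf.sum(axis=(0, 2))))
        if x.requires_grad:
            dcols = np.einsum("ok,nop->nkp", wmat, gf, optimize=True)
            grads.append((x, _col2im(dcols, x.data.shape, kh, kw, stride, pad, ho, wo)))
        return grads

    return _node(data, tuple(t for t in (x, weight, bias) if t is not None), backward)


# -- fused losses ----------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_softmax_ce(logits: Tensor, labels: np.ndarray,
                        class_weights: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Class-weighted cross-entropy: sum_i w_{y_i} * (-log p_{y_i}) / sum_i w_{y_i}."""
    labels = np.asarray(labels, dtype=np.int64)
    w = np.asarray(class_weights, dtype=np.float64)[labels]
    p = softmax(logits.data.astype(np.float64))
    n = logits.data.shape[0]
    py = np.clip(p[np.arange(n), labels], eps, None)
    wsum = w.sum()
    loss = float((-w * np.log(py)).sum() / wsum)

    def backward(g):
        onehot = np.zeros_like(p)
        onehot[np.arange(n), labels] = 1.0
        dl = (p - onehot) * (w / wsum)[:, None]
        return [(logits, (g * dl).astype(DTYPE))]

    return _node(np.asarray(loss), (logits,), backward)
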