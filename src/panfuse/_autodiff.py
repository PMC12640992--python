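"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough tensor machinery to express and train the cross-fusion network:
broadcasting elementwise ops, (batched) matmul, 1-D convolution and max
pooling via im2col, activations, softmax / log-softmax, reductions, slicing
and concatenation. Gradients are accumulated by topological-order backward
passes; every op's backward is exercised by finite-difference checks in the
test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=float))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- elementwise --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("tensor division only supports constants")
        return self * (1.0 / scalar)

    # -- matmul -------------------------------------------------------------

    def matmul(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        return self._make(np.matmul(a, b), (self, other), backward)

    __matmul__ = matmul

    # -- activations --------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    # -- reductions / reshapes ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / count

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        return self._make(self.data[key], (self,), backward)

    # -- softmax family ------------------------------------------------------

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accumulate(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    def log_softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        soft = np.exp(out_data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    # -- conv / pool (1-D, NCL layout) ---------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor", stride: int = 1, padding: int = 0):
        """1-D convolution; input (B, C_in, L), weight (C_out, C_in, K)."""
        x = self.data
        B, C_in, L = x.shape
        C_out, _, K = weight.data.shape
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
        Lp = x.shape[2]
        L_out = (Lp - K) // stride + 1
        # im2col: (B, C_in, K, L_out)
        idx = stride * np.arange(L_out)[None, :] + np.arange(K)[:, None]  # (K, L_out)
        cols = x[:, :, idx]  # (B, C_in, K, L_out)
        cols2 = cols.reshape(B, C_in * K, L_out)
        W2 = weight.data.reshape(C_out, C_in * K)
        out_data = np.einsum("ok,bkl->bol", W2, cols2) + bias.data[None, :, None]

        def backward(g):
            # g: (B, C_out, L_out)
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2)))
            if weight.requires_grad:
                gW2 = np.einsum("bol,bkl->ok", g, cols2)
                weight._accumulate(gW2.reshape(C_out, C_in, K))
            if self.requires_grad:
                gcols2 = np.einsum("ok,bol->bkl", W2, g)
                gcols = gcols2.reshape(B, C_in, K, L_out)
                gx = np.zeros_like(x)
                np.add.at(gx, (slice(None), slice(None), idx), gcols)
                if padding:
                    gx = gx[:, :, padding : padding + L]
                self._accumulate(gx)

        return self._make(out_data, (self, weight, bias), backward)

    def maxpool1d(self, kernel: int = 2):
        """Non-overlapping 1-D max pooling over the last axis (trailing
        remainder dropped)."""
        x = self.data
        B, C, L = x.shape
        L_out = L // kernel
        windows = x[:, :, : L_out * kernel].reshape(B, C, L_out, kernel)
        arg = windows.argmax(axis=3)
        out_data = np.take_along_axis(windows, arg[..., None], axis=3)[..., 0]

        def backward(g):
            if self.requires_grad:
                gw = np.zeros_like(windows)
                np.put_along_axis(gw, arg[..., None], g[..., None], axis=3)
                gx = np.zeros_like(x)
                gx[:, :, : L_out * kernel] = gw.reshape(B, C, L_out * kernel)
                self._accumulate(gx)

        return self._make(out_data, (self,), backward)


def concat(tensors, axis=0):
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors, axis=0):
    expanded = []
    for t in tensors:
        t = t if isinstance(t, Tensor) else Tensor(t)
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else t.data.ndim + 1 + axis, 1)
        expanded.append(t.reshape(*shape))
    return concat(expanded, axis=axis)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy between class logits (B, k) and integer targets."""
    targets = np.asarray(targets, dtype=int)
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(targets.size), targets]
    return -picked.mean()


class Adam:
    """Adaptive-moment optimiser over a flat parameter list."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
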