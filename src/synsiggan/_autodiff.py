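"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to train the recurrent generator and convolutional
discriminator: a tape of `Tensor` nodes built by the op functions below and
unwound by :meth:`Tensor.backward`.  Every op accepts plain ndarrays as well
as Tensors and only records a tape node when at least one input is a Tensor,
so forward-only code paths (sampling, evaluation) pay no tape overhead.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "is_tensor", "data_of", "matmul", "add", "mul", "neg",
    "sigmoid", "tanh", "relu", "concat", "slice_cols", "conv1d", "maxpool1d",
    "reshape", "log_softmax", "mean_of_col", "Adam",
]


class Tensor:
    """An ndarray plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to the reflected operators below
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self):
        """Accumulate d(self)/d(leaf) into every reachable leaf's .grad."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()
        stack = [(self, False)]        # iterative DFS: graphs can be deep
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if isinstance(p, Tensor) and id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not isinstance(parent, Tensor):
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # convenience operator sugar (numpy operand allowed on either side)
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def is_tensor(x):
    return isinstance(x, Tensor)


def data_of(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _any_tensor(*xs):
    return any(isinstance(x, Tensor) for x in xs)


def _node(data, parents, backward):
    # parents keeps its full positional alignment with the backward closure;
    # non-Tensor entries are skipped during the backward pass
    if not any(isinstance(p, Tensor) for p in parents):
        return data
    return Tensor(data, parents=tuple(parents), backward=backward)


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def matmul(a, b):
    ad, bd = data_of(a), data_of(b)
    out = ad @ bd

    def backward(g):
        ga = g @ bd.swapaxes(-1, -2) if isinstance(a, Tensor) else None
        gb = ad.swapaxes(-1, -2) @ g if isinstance(b, Tensor) else None
        return (ga, gb)

    return _node(out, (a, b), backward)


def add(a, b):
    ad, bd = data_of(a), data_of(b)
    out = ad + bd

    def backward(g):
        ga = _unbroadcast(g, ad.shape) if isinstance(a, Tensor) else None
        gb = _unbroadcast(g, bd.shape) if isinstance(b, Tensor) else None
        return (ga, gb)

    return _node(out, (a, b), backward)


def mul(a, b):
    ad, bd = data_of(a), data_of(b)
    out = ad * bd

    def backward(g):
        ga = _unbroadcast(g * bd, ad.shape) if isinstance(a, Tensor) else None
        gb = _unbroadcast(g * ad, bd.shape) if isinstance(b, Tensor) else None
        return (ga, gb)

    return _node(out, (a, b), backward)


def neg(a):
    out = -data_of(a)
    return _node(out, (a,), lambda g: (-g,))


def sigmoid(a):
    ad = data_of(a)
    out = np.empty_like(ad)
    pos = ad >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-ad[pos]))
    e = np.exp(ad[~pos])
    out[~pos] = e / (1.0 + e)
    return _node(out, (a,), lambda g: (g * out * (1.0 - out),))


def tanh(a):
    out = np.tanh(data_of(a))
    return _node(out, (a,), lambda g: (g * (1.0 - out * out),))


def relu(a):
    ad = data_of(a)
    out = np.maximum(ad, 0.0)
    return _node(out, (a,), lambda g: (g * (ad > 0),))


def concat(parts, axis=-1):
    datas = [data_of(p) for p in parts]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple(pc if isinstance(p, Tensor) else None
                     for p, pc in zip(parts, pieces))

    return _node(out, tuple(parts), backward)


def slice_cols(a, start, stop):
    ad = data_of(a)
    out = ad[..., start:stop]

    def backward(g):
        full = np.zeros_like(ad)
        full[..., start:stop] = g
        return (full,)

    return _node(out, (a,), backward)


def reshape(a, shape):
    ad = data_of(a)
    out = ad.reshape(shape)
    return _node(out, (a,), lambda g: (g.reshape(ad.shape),))


def conv1d(x, w, b, stride=1):
    """Valid-mode 1-D convolution.

    x: (B, T, Cin); w: (K, Cin, Cout); b: (Cout,) -> (B, L, Cout)
    with L = floor((T-K)/stride) + 1.
    """
    xd, wd, bd = data_of(x), data_of(w), data_of(b)
    B, T, cin = xd.shape
    K = wd.shape[0]
    if T < K:
        raise ValueError(f"input length {T} shorter than kernel {K}")
    L = (T - K) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xd, K, axis=1)  # (B,T-K+1,Cin,K)
    win = win[:, ::stride]                                         # (B,L,Cin,K)
    out = np.einsum("blck,kcf->blf", win, wd) + bd

    def backward(g):
        gw = np.einsum("blck,blf->kcf", win, g) if isinstance(w, Tensor) else None
        gb = g.sum(axis=(0, 1)) if isinstance(b, Tensor) else None
        gx = None
        if isinstance(x, Tensor):
            gx = np.zeros_like(xd)
            gwin = np.einsum("blf,kcf->blck", g, wd)
            starts = np.arange(L) * stride
            for k in range(K):
                np.add.at(gx, (slice(None), starts + k, slice(None)),
                          gwin[:, :, :, k])
        return (gx, gw, gb)

    return _node(out, (x, w, b), backward)


def maxpool1d(x, size):
    """Non-overlapping max pooling along axis 1; trailing remainder dropped."""
    xd = data_of(x)
    B, L, C = xd.shape
    L2 = L // size
    if L2 < 1:
        raise ValueError(f"pool size {size} exceeds length {L}")
    blocks = xd[:, :L2 * size].reshape(B, L2, size, C)
    arg = blocks.argmax(axis=2)
    out = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(g):
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, arg[:, :, None, :], g[:, :, None, :], axis=2)
        gx = np.zeros_like(xd)
        gx[:, :L2 * size] = gb.reshape(B, L2 * size, C)
        return (gx,)

    return _node(out, (x,), backward)


def log_softmax(a):
    ad = data_of(a)
    m = ad.max(axis=-1, keepdims=True)
    z = ad - m
    out = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))

    def backward(g):
        sm = np.exp(out)
        return (g - sm * g.sum(axis=-1, keepdims=True),)

    return _node(out, (a,), backward)


def mean_of_col(a, col):
    """Mean of one column of a 2-D node -> scalar."""
    ad = data_of(a)
    n = ad.shape[0]
    out = ad[:, col].mean()

    def backward(g):
        full = np.zeros_like(ad)
        full[:, col] = g / n
        return (full,)

    return _node(np.asarray(out), (a,), backward)


class Adam:
    """Adam with bias correction over a flat list of leaf Tensors."""

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
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
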