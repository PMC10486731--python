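"""Minimal reverse-mode autodiff engine for small 3D convolutional networks.

Implements exactly the operations the volumetric classifiers in this package
need — 3D convolution (dense and depthwise), batch normalisation, max/average
pooling, global average pooling, fully connected layers, the usual
activations, channel concatenation and softmax cross-entropy — together with
an Adam optimiser and exponential learning-rate decay.  Everything runs on
float32 numpy arrays; convolutions are lowered to matrix multiplications via
``sliding_window_view`` so the heavy lifting is done by BLAS.

Gradients are computed by building a tape of ``Tensor`` nodes during the
forward pass and walking it in reverse topological order.  Wrapping inference
in :func:`no_grad` skips tape construction entirely.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable gradient-tape construction inside the context."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents if _GRAD_ENABLED else ()
        self._backward = backward if _GRAD_ENABLED else None

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the tape as we go
            node._backward = None
            node._parents = ()

    def item(self) -> float:
        return float(self.data)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*ts: Tensor) -> bool:
    return _GRAD_ENABLED and any(t.requires_grad or t._parents for t in ts)


def _make(data, parents, backward, *inputs: Tensor) -> Tensor:
    if _needs_graph(*inputs):
        return Tensor(data, requires_grad=False, parents=parents, backward=backward)
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def bwd(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bwd, a, b)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def bwd(g):
        a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bwd, a, b)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def bwd(g):
        x.accumulate(g * mask)

    return _make(out, (x,), bwd, x)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x.accumulate(g * s * (1.0 - s))

    return _make(s, (x,), bwd, x)


def silu(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = x.data * s

    def bwd(g):
        x.accumulate(g * (s * (1.0 + x.data * (1.0 - s))))

    return _make(out, (x,), bwd, x)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t.accumulate(piece)

    return _make(out, tuple(tensors), bwd, *tensors)


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.data.shape
    out = x.data.reshape(shape)

    def bwd(g):
        x.accumulate(g.reshape(orig))

    return _make(out, (x,), bwd, x)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        return tuple(int(i) for i in v)  # type: ignore[return-value]
    return (int(v),) * 3


def _pad5(x: np.ndarray, pad: tuple[int, int, int]) -> np.ndarray:
    if any(pad):
        return np.pad(x, ((0, 0), (0, 0), (pad[0], pad[0]),
                          (pad[1], pad[1]), (pad[2], pad[2])))
    return x


def _windows(xp: np.ndarray, k: tuple, s: tuple) -> np.ndarray:
    # (B, C, Do, Ho, Wo, kd, kh, kw)
    v = sliding_window_view(xp, k, axis=(2, 3, 4))
    return v[:, :, ::s[0], ::s[1], ::s[2]]


def _col2im(dcols: np.ndarray, xp_shape: tuple, k: tuple, s: tuple,
            pad: tuple) -> np.ndarray:
    """Scatter (B, C, Do, Ho, Wo, kd, kh, kw) gradients back onto the input."""
    B, C = xp_shape[0], xp_shape[1]
    Do, Ho, Wo = dcols.shape[2], dcols.shape[3], dcols.shape[4]
    dxp = np.zeros(xp_shape, dtype=np.float32)
    for a in range(k[0]):
        for b in range(k[1]):
            for c in range(k[2]):
                dxp[:, :, a:a + s[0] * Do:s[0],
                    b:b + s[1] * Ho:s[1],
                    c:c + s[2] * Wo:s[2]] += dcols[:, :, :, :, :, a, b, c]
    if any(pad):
        sl = tuple([slice(None), slice(None)] +
                   [slice(p, dim - p) for p, dim in zip(pad, xp_shape[2:])])
        dxp = dxp[sl]
    return dxp


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, padding=0) -> Tensor:
    """Dense 3D convolution; ``w`` has shape (O, C, kd, kh, kw)."""
    s, pad = _triple(stride), _triple(padding)
    k = w.data.shape[2:]
    xp = _pad5(x.data, pad)
    v = _windows(xp, k, s)
    B, C, Do, Ho, Wo = v.shape[:5]
    O = w.data.shape[0]
    CK = C * k[0] * k[1] * k[2]
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(-1, CK)
    wmat = w.data.reshape(O, CK)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out = out.reshape(B, Do, Ho, Wo, O).transpose(0, 4, 1, 2, 3)
    out = np.ascontiguousarray(out)

    inputs = (x, w) if b is None else (x, w, b)
    if not _needs_graph(*inputs):
        return Tensor(out)

    def bwd(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, O)
        if w.requires_grad or w._parents:
            w.accumulate((gmat.T @ cols).reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._parents):
            b.accumulate(gmat.sum(axis=0))
        if x.requires_grad or x._parents:
            dcols = (gmat @ wmat).reshape(B, Do, Ho, Wo, C, *k)
            dcols = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
            x.accumulate(_col2im(dcols, xp.shape, k, s, pad))

    return Tensor(out, parents=inputs, backward=bwd)


def depthwise_conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride=1, padding=0) -> Tensor:
    """Per-channel 3D convolution; ``w`` has shape (C, kd, kh, kw)."""
    s, pad = _triple(stride), _triple(padding)
    k = w.data.shape[1:]
    xp = _pad5(x.data, pad)
    v = _windows(xp, k, s)  # (B, C, Do, Ho, Wo, kd, kh, kw)
    out = np.einsum("bcdhwijk,cijk->bcdhw", v, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None, None]
    out = np.ascontiguousarray(out, dtype=np.float32)

    inputs = (x, w) if b is None else (x, w, b)
    if not _needs_graph(*inputs):
        return Tensor(out)

    B, C, Do, Ho, Wo = out.shape

    def bwd(g):
        if w.requires_grad or w._parents:
            w.accumulate(np.einsum("bcdhwijk,bcdhw->cijk", v, g, optimize=True))
        if b is not None and (b.requires_grad or b._parents):
            b.accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad or x._parents:
            dcols = g[..., None, None, None] * w.data[None, :, None, None, None, :, :, :]
            x.accumulate(_col2im(dcols, xp.shape, k, s, pad))

    return Tensor(out, parents=inputs, backward=bwd)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def maxpool3d(x: Tensor, kernel=3, stride=2, padding=1) -> Tensor:
    k, s, pad = _triple(kernel), _triple(stride), _triple(padding)
    xp = x.data
    if any(pad):
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad[0], pad[0]),
                             (pad[1], pad[1]), (pad[2], pad[2])),
                    constant_values=-np.inf)
    v = _windows(xp, k, s)
    B, C, Do, Ho, Wo = v.shape[:5]
    flat = v.reshape(B, C, Do, Ho, Wo, -1)
    arg = flat.argmax(axis=-1)
    out = np.ascontiguousarray(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0])

    if not _needs_graph(x):
        return Tensor(out)

    def bwd(g):
        dxp = np.zeros(xp.shape, dtype=np.float32)
        nk = k[0] * k[1] * k[2]
        for j in range(nk):
            mask = arg == j
            if not mask.any():
                continue
            a, rem = divmod(j, k[1] * k[2])
            b_, c = divmod(rem, k[2])
            dxp[:, :, a:a + s[0] * Do:s[0], b_:b_ + s[1] * Ho:s[1],
                c:c + s[2] * Wo:s[2]] += g * mask
        if any(pad):
            dxp = dxp[:, :, pad[0]:dxp.shape[2] - pad[0],
                      pad[1]:dxp.shape[3] - pad[1], pad[2]:dxp.shape[4] - pad[2]]
        x.accumulate(dxp)

    return Tensor(out, parents=(x,), backward=bwd)


def avgpool3d(x: Tensor, kernel=2, stride=2, ceil_mode: bool = True) -> Tensor:
    """Average pooling with count-excluding zero padding when ceil_mode pads."""
    k, s = _triple(kernel), _triple(stride)
    spatial = x.data.shape[2:]
    if ceil_mode:
        out_sp = tuple(-(-d // st) for d, st in zip(spatial, s))
    else:
        out_sp = tuple((d - kk) // st + 1 for d, kk, st in zip(spatial, k, s))
    need = tuple((o - 1) * st + kk for o, kk, st in zip(out_sp, s, k))
    pad_r = tuple(max(0, n - d) for n, d in zip(need, spatial))
    xp = x.data
    counts = np.ones((1, 1) + spatial, dtype=np.float32)
    if any(pad_r):
        pads = ((0, 0), (0, 0), (0, pad_r[0]), (0, pad_r[1]), (0, pad_r[2]))
        xp = np.pad(xp, pads)
        counts = np.pad(counts, pads)
    v = _windows(xp, k, s)
    cnt = _windows(counts, k, s).sum(axis=(-1, -2, -3))
    out = v.sum(axis=(-1, -2, -3)) / cnt
    out = np.ascontiguousarray(out, dtype=np.float32)

    if not _needs_graph(x):
        return Tensor(out)

    B, C, Do, Ho, Wo = out.shape

    def bwd(g):
        gn = g / cnt
        dxp = np.zeros(xp.shape, dtype=np.float32)
        for a in range(k[0]):
            for b_ in range(k[1]):
                for c in range(k[2]):
                    dxp[:, :, a:a + s[0] * Do:s[0], b_:b_ + s[1] * Ho:s[1],
                        c:c + s[2] * Wo:s[2]] += gn
        dxp = dxp[:, :, :spatial[0], :spatial[1], :spatial[2]]
        x.accumulate(dxp)

    return Tensor(out, parents=(x,), backward=bwd)


def global_avgpool3d(x: Tensor) -> Tensor:
    out = x.data.mean(axis=(2, 3, 4))
    n = np.prod(x.data.shape[2:])

    def bwd(g):
        x.accumulate(np.broadcast_to(
            (g / n)[:, :, None, None, None], x.data.shape).astype(np.float32))

    return _make(out, (x,), bwd, x)


# ---------------------------------------------------------------------------
# dense layer and losses
# ---------------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    out = x.data @ w.data.T
    if b is not None:
        out = out + b.data
    inputs = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if w.requires_grad or w._parents:
            w.accumulate(g.T @ x.data)
        if b is not None and (b.requires_grad or b._parents):
            b.accumulate(g.sum(axis=0))
        if x.requires_grad or x._parents:
            x.accumulate(g @ w.data)

    return _make(out, inputs, bwd, *inputs)


def log_softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.exp(log_softmax(np.asarray(logits, dtype=np.float64), axis=axis))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of integer labels."""
    labels = np.asarray(labels, dtype=np.int64)
    ls = log_softmax(logits.data.astype(np.float64))
    B = labels.shape[0]
    loss = -ls[np.arange(B), labels].mean()

    def bwd(g):
        p = np.exp(ls)
        p[np.arange(B), labels] -= 1.0
        logits.accumulate((g * p / B).astype(np.float32))

    return _make(np.float32(loss), (logits,), bwd, logits)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class; children/parameters discovered from instance attributes."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    out.append(v)
        return out

    def buffers(self) -> list[np.ndarray]:
        out = []
        for m in self.modules():
            for name in getattr(m, "_buffer_names", ()):
                out.append(getattr(m, name))
        return out

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        """Copies of every parameter and buffer, in deterministic order."""
        return [p.data.copy() for p in self.parameters()] + \
               [b.copy() for b in self.buffers()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        bufs = self.buffers()
        assert len(arrays) == len(params) + len(bufs)
        for p, a in zip(params, arrays):
            p.data[...] = a
        for b, a in zip(bufs, arrays[len(params):]):
            b[...] = a

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel=3, stride=1, padding=0,
                 bias: bool = False, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = _triple(kernel)
        fan_in = in_ch * k[0] * k[1] * k[2]
        self.weight = Parameter(he_init(rng, (out_ch, in_ch) + k, fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv3d(Module):
    def __init__(self, ch: int, kernel=3, stride=1, padding=1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = _triple(kernel)
        fan_in = k[0] * k[1] * k[2]
        self.weight = Parameter(he_init(rng, (ch,) + k, fan_in))
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv3d(x, self.weight, None, self.stride, self.padding)


class BatchNorm3d(Module):
    """Batch normalisation over (B, spatial) with running statistics."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._buffer_names = ("running_mean", "running_var")
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            axes = (0, 2, 3, 4)
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None, None]) * inv[None, :, None, None, None]
        out = xhat * self.gamma.data[None, :, None, None, None] + \
            self.beta.data[None, :, None, None, None]

        gamma, beta, training = self.gamma, self.beta, self.training
        if not _needs_graph(x, gamma, beta):
            return Tensor(out.astype(np.float32))

        def bwd(g):
            axes = (0, 2, 3, 4)
            if gamma.requires_grad:
                gamma.accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta.accumulate(g.sum(axis=axes))
            if x.requires_grad or x._parents:
                gi = g * gamma.data[None, :, None, None, None]
                if training:
                    n = g.shape[0] * g.shape[2] * g.shape[3] * g.shape[4]
                    t1 = gi.sum(axis=axes, keepdims=True)
                    t2 = (gi * xhat).sum(axis=axes, keepdims=True)
                    dx = inv[None, :, None, None, None] * (gi - t1 / n - xhat * t2 / n)
                else:
                    dx = gi * inv[None, :, None, None, None]
                x.accumulate(dx.astype(np.float32))

        return Tensor(out.astype(np.float32), parents=(x, gamma, beta), backward=bwd)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_f)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_f, in_f)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_f, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return silu(x)


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class ExponentialLR:
    """Multiplies the optimiser learning rate by ``gamma`` each epoch."""

    def __init__(self, optimizer: Adam, gamma: float):
        self.optimizer = optimizer
        self.gamma = gamma

    def step(self):
        self.optimizer.lr *= self.gamma
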