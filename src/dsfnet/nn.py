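"""Reverse-mode automatic differentiation and neural-network layers on numpy.

This is the numerical backbone of the package: a small define-by-run tensor
graph (:class:`Tensor`), the layer set the fusion network needs (1-D
convolution, batch/layer normalisation, dropout, linear maps, multi-head
self-attention) and an Adam optimiser.  Everything is plain numpy; float32 is
the working precision for training, float64 graphs are supported for
gradient checking.

Gradients flow to any leaf tensor with ``requires_grad=True`` — model
parameters during training, and the *inputs* during Integrated-Gradients
attribution.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

# ---------------------------------------------------------------------------
# Tensor graph
# ---------------------------------------------------------------------------

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference / metric evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_children")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._children: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, children, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(c.requires_grad for c in children):
            out.requires_grad = True
            out._children = children
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative post-order topological sort (no recursion, no closure
        # cycle: a self-referencing visit() closure would keep every graph
        # node alive until a full gc pass)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            t, processed = stack.pop()
            if processed:
                topo.append(t)
                continue
            if id(t) in seen or not t.requires_grad:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for c in t._children:
                stack.append((c, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                # free the subgraph as we go: intermediate grads and closures
                # are dead once a node's backward has run (leaves keep theirs)
                t.grad = None
                t._backward = None
                t._children = ()
        topo.clear()

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, p: float):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data ** p, (a,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        # numerically stable two-branch sigmoid
        x = a.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, 0, None))),
                            np.exp(np.clip(x, None, 0)) / (1.0 + np.exp(np.clip(x, None, 0))))

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def softplus(self):
        """log(1 + exp(x)), stable: max(x,0) + log1p(exp(-|x|))."""
        a = self
        x = a.data
        out_data = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

        def backward(g):
            if a.requires_grad:
                a._accum(g * sig)

        return Tensor._make(out_data, (a,), backward)

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy()
                         if np.ndim(g) else np.full_like(a.data, g))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(a.data, axes), (a,), backward)

    def __getitem__(self, key):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, key, g)
                a._accum(full)

        return Tensor._make(a.data[key], (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = Tensor(np.max(x.data, axis=axis, keepdims=True))  # constant shift
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple,
                     eps: float):
    """Fused training-mode batch norm over `axes`.

    Returns (out, batch_mean, batch_var) with the statistics as plain arrays
    (for the running-average update).  A single graph node instead of the
    ~8 the composed form would create — keeps large conv activations from
    piling up in the autodiff graph.
    """
    mean = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    bshape = mean.shape
    g = gamma.data.reshape(bshape)
    out_data = xhat * g + beta.data.reshape(bshape)
    m = x.data.size / mean.size

    def backward(grad):
        if gamma.requires_grad:
            gamma._accum((grad * xhat).sum(axis=axes).reshape(gamma.data.shape))
        if beta.requires_grad:
            beta._accum(grad.sum(axis=axes).reshape(beta.data.shape))
        if x.requires_grad:
            gx_hat = grad * g
            term = (gx_hat.sum(axis=axes, keepdims=True)
                    + xhat * (gx_hat * xhat).sum(axis=axes, keepdims=True)) / m
            x._accum(inv_std * (gx_hat - term))

    out = Tensor._make(out_data, (x, gamma, beta), backward)
    return out, mean.reshape(-1), var.reshape(-1)


def dropout_op(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout as one node; the kept-mask is stored as bool."""
    keep = rng.random(x.data.shape, dtype=np.float32) >= p
    scale = x.data.dtype.type(1.0 / (1.0 - p))

    def backward(g):
        if x.requires_grad:
            x._accum(np.where(keep, g * scale, 0))

    return Tensor._make(np.where(keep, x.data * scale, 0), (x,), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int, padding: int) -> Tensor:
    """1-D convolution (cross-correlation). x: (N,C,L), weight: (O,C,K)."""
    n, c, length = x.data.shape
    o, c2, k = weight.data.shape
    if c != c2:
        raise ValueError(f"conv1d channel mismatch: input {c}, weight {c2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    l_out = (length + 2 * padding - k) // stride + 1
    # cols: (N, C, l_out, K)
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::stride][:, :, :l_out]
    cols_m = cols.transpose(0, 2, 1, 3).reshape(n * l_out, c * k)
    w_m = weight.data.reshape(o, c * k)
    y = (cols_m @ w_m.T).reshape(n, l_out, o).transpose(0, 2, 1)
    if bias is not None:
        y = y + bias.data[None, :, None]
    children = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        # g: (N, O, l_out)
        g_m = g.transpose(0, 2, 1).reshape(n * l_out, o)
        if weight.requires_grad:
            gw = (g_m.T @ cols_m).reshape(o, c, k)
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = (g_m @ w_m).reshape(n, l_out, c, k).transpose(0, 2, 1, 3)
            dxp = np.zeros_like(xp)
            for kk in range(k):  # stride-strided scatter, k small (7)
                dxp[:, :, kk:kk + stride * l_out:stride] += dcols[:, :, :, kk]
            x._accum(dxp[:, :, padding:padding + length]
                     if padding else dxp)

    return Tensor._make(y, children, backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_buffers(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data = value.astype(params[name].data.dtype).reshape(
                    params[name].data.shape)
            else:
                obj = self
                parts = name.split(".")
                for p in parts[:-1]:
                    obj = obj[int(p)] if isinstance(obj, (list, tuple)) else getattr(obj, p)
                setattr(obj, parts[-1], value.copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Tensor(rng.uniform(-bound, bound, (in_features, out_features)
                                         ).astype(dtype), requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, out_features).astype(dtype),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, padding: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.stride, self.padding = stride, padding
        bound = 1.0 / math.sqrt(in_channels * kernel_size)
        self.weight = Tensor(rng.uniform(-bound, bound,
                                         (out_channels, in_channels, kernel_size)
                                         ).astype(dtype), requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, out_channels).astype(dtype),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride, self.padding)

    def out_length(self, length: int) -> int:
        k = self.weight.shape[2]
        return (length + 2 * self.padding - k) // self.stride + 1


class BatchNorm1d(Module):
    """Batch normalisation over (N, C) or (N, C, L) inputs."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(num_features, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            axes, shape = (0,), (1, -1)
        else:
            axes, shape = (0, 2), (1, -1, 1)
        if self.training:
            out, mean, var = batch_norm_train(x, self.gamma, self.beta, axes, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var
                                + m * var).astype(self.running_var.dtype)
            return out
        mean = Tensor(self.running_mean.reshape(shape))
        var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mean) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        return (x - mean) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1): {p}")
        self.p, self.rng = p, rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        return dropout_op(x, self.p, self.rng)


class MultiheadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"d_model {d_model} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.qkv = Linear(d_model, 3 * d_model, rng, dtype)
        self.out = Linear(d_model, d_model, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = self.qkv(x).reshape(b, t, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # (B, H, T, dh)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer (attention + position-wise feed-forward)."""

    def __init__(self, d_model: int, n_heads: int, dim_ff: int, dropout: float,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.attn = MultiheadSelfAttention(d_model, n_heads, rng, dtype)
        self.ln1 = LayerNorm(d_model, dtype=dtype)
        self.ff1 = Linear(d_model, dim_ff, rng, dtype)
        self.ff2 = Linear(dim_ff, d_model, rng, dtype)
        self.ln2 = LayerNorm(d_model, dtype=dtype)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)
        self.drop_ff = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.drop1(self.attn(x)))
        ff = self.ff2(self.drop_ff(self.ff1(x).relu()))
        return self.ln2(x + self.drop2(ff))


class Adam:
    """Adam optimiser with bias correction (Kingma & Ba defaults)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
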