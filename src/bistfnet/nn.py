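"""Neural-network layers on top of :mod:`bistfnet.autodiff`.

Layers follow the usual conventions: a :class:`Module` owns named
:class:`Parameter` tensors and sub-modules, ``parameters()`` walks the tree,
and ``state_dict``/``load_state_dict`` snapshot raw arrays (used for
checkpointing).  Parameter initialization is always driven by an explicit
``numpy.random.Generator`` so model construction is deterministic.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, conv3d, stack

DTYPE = np.float64


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE))
        # trainable regardless of any no_grad() context active at creation
        self.requires_grad = True


class Module:
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data = state[name].copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        if zero_init:
            self.W = Parameter(np.zeros((in_features, out_features)))
        else:
            self.W = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.b = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel, stride, padding, rng: np.random.Generator):
        kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.padding = tuple(padding)
        fan_in = in_ch * int(np.prod(kernel))
        self.W = Parameter(_kaiming(rng, (out_ch, in_ch) + kernel, fan_in))
        self.b = Parameter(np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.W, self.b, self.stride, self.padding)


class LayerNorm(Module):
    """Normalization over the last axis with learned affine parameters."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class ChannelNorm(Module):
    """Per-channel normalization of a (B, C, D, H, W) block over (D, H, W)."""

    def __init__(self, n_channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        shape = (1, -1, 1, 1, 1)
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)


def _pool_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Adaptive average-pooling matrix (n_out x n_in): each output cell
    averages the input range [floor(i*n/m), ceil((i+1)*n/m))."""
    M = np.zeros((n_out, n_in), dtype=DTYPE)
    for i in range(n_out):
        lo = (i * n_in) // n_out
        hi = -(-((i + 1) * n_in) // n_out)  # ceil
        M[i, lo:hi] = 1.0 / (hi - lo)
    return M


def _linear_resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Linear-interpolation (align_corners) resize matrix (n_out x n_in)."""
    M = np.zeros((n_out, n_in), dtype=DTYPE)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    for i in range(n_out):
        p = i * (n_in - 1) / (n_out - 1) if n_out > 1 else 0.0
        lo = int(math.floor(p))
        hi = min(lo + 1, n_in - 1)
        w = p - lo
        M[i, lo] += 1.0 - w
        M[i, hi] += w
    return M


class AdaptiveAvgPool3d(Module):
    """Separable adaptive average pooling of (B, C, D, H, W) to fixed sizes."""

    def __init__(self, out_sizes):
        self.out_sizes = tuple(out_sizes)

    def forward(self, x: Tensor) -> Tensor:
        for k, n_out in enumerate(self.out_sizes):
            axis = 2 + k
            x = x.axis_dot(_pool_matrix(x.shape[axis], n_out), axis)
        return x


def trilinear_resize(x: Tensor, out_sizes) -> Tensor:
    """Trilinear resize of (B, C, D, H, W) to `out_sizes` (separable)."""
    for k, n_out in enumerate(out_sizes):
        axis = 2 + k
        x = x.axis_dot(_linear_resize_matrix(x.shape[axis], n_out), axis)
    return x


class MultiheadAttention(Module):
    """Multi-head scaled dot-product attention.

    With ``project_kv=False`` the key and value streams are used as-is
    (the literal "sequence serves as both key and value" reading); otherwise
    learned K/V projections are applied.  ``zero_init_out`` zeroes the output
    projection so the module starts as a null branch under a residual
    connection.  The attention weights of the last forward pass are kept in
    ``last_weights`` (B, heads, N, M) for diagnostics.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 project_kv: bool = True, zero_init_out: bool = False):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.Wq = Linear(d_model, d_model, rng)
        self.project_kv = project_kv
        if project_kv:
            self.Wk = Linear(d_model, d_model, rng)
            self.Wv = Linear(d_model, d_model, rng)
        self.Wo = Linear(d_model, d_model, rng, zero_init=zero_init_out)
        self.last_weights: np.ndarray | None = None

    def _split(self, t: Tensor) -> Tensor:
        B, N, _ = t.shape
        return t.reshape(B, N, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def forward(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        B, N, _ = q.shape
        Q = self._split(self.Wq(q))
        K = self._split(self.Wk(k) if self.project_kv else k)
        V = self._split(self.Wv(v) if self.project_kv else v)
        scores = (Q @ K.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_k))
        attn = scores.softmax(axis=-1)
        self.last_weights = attn.data.copy()
        ctx = attn @ V  # B, h, N, d_k
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, N, self.d_model)
        return self.Wo(ctx)


class GRUCell(Module):
    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.hidden_size = hidden_size
        self.Wx = Parameter(_kaiming(rng, (input_size, 3 * hidden_size), input_size))
        self.Wh = Parameter(_kaiming(rng, (hidden_size, 3 * hidden_size), hidden_size))
        self.bx = Parameter(np.zeros(3 * hidden_size))
        self.bh = Parameter(np.zeros(3 * hidden_size))

    def forward(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.hidden_size
        gx = x @ self.Wx + self.bx
        gh = h @ self.Wh + self.bh
        r = (gx[:, :H] + gh[:, :H]).sigmoid()
        z = (gx[:, H:2 * H] + gh[:, H:2 * H]).sigmoid()
        n = (gx[:, 2 * H:] + r * gh[:, 2 * H:]).tanh()
        return (1.0 - z) * n + z * h


class BiGRU(Module):
    """Bidirectional GRU over (B, T, F); output (B, T, 2*hidden)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.hidden_size = hidden_size
        self.fwd = GRUCell(input_size, hidden_size, rng)
        self.bwd = GRUCell(input_size, hidden_size, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.hidden_size), dtype=x.dtype))
        outs_f = []
        for t in range(T):
            h = self.fwd(x[:, t, :], h)
            outs_f.append(h)
        h = Tensor(np.zeros((B, self.hidden_size), dtype=x.dtype))
        outs_b = [None] * T
        for t in reversed(range(T)):
            h = self.bwd(x[:, t, :], h)
            outs_b[t] = h
        f = stack(outs_f, axis=1)
        b = stack(outs_b, axis=1)
        return concat([f, b], axis=2)
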