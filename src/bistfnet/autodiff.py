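"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` runs reverse-mode accumulation through the
recorded graph.  Only the operations needed by the network layers are
implemented (broadcasted arithmetic, batched matmul, reshape/transpose/slice,
reductions, pointwise nonlinearities, a 3-D convolution and a constant-matrix
axis contraction used for pooling / trilinear resizing).

Gradient correctness for every op is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "no_grad"]


class _NoGrad:
    """Context manager that disables graph recording (inference mode)."""

    _active = False

    def __enter__(self):
        self._prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) and not _NoGrad._active
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if not _NoGrad._active and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd engine ------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other
        out_data = a.data / b.data

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * out_data / b.data, b.shape))

        return Tensor._make(out_data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data ** p, (a,), bwd)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        in_shape = a.shape

        def bwd(g):
            if a.requires_grad:
                a._accum(g.reshape(in_shape))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._make(a.data[idx], (a,), bwd)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bwd(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy() if np.ndim(g) else np.full(a.shape, g, dtype=a.dtype))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(gg, axis)
                a._accum(np.broadcast_to(gg, a.shape).astype(a.dtype, copy=True))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.shape[ax] for ax in axis]))
        else:
            n = self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise ------------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bwd)

    # -- softmax / logsumexp (numerically stable compositions) ----------------
    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    # -- constant-matrix contraction along one axis ---------------------------
    def axis_dot(self, mat: np.ndarray, axis: int) -> "Tensor":
        """Contract `self` with a constant matrix along `axis`.

        out[..., i, ...] = sum_j mat[i, j] * self[..., j, ...]

        Used for adaptive average pooling, trilinear resizing and topographic
        interpolation, all of which are fixed linear maps.
        """
        a = self
        moved = np.moveaxis(a.data, axis, -1)
        out = np.moveaxis(moved @ mat.T, -1, axis)

        def bwd(g):
            if a.requires_grad:
                gm = np.moveaxis(g, axis, -1)
                a._accum(np.moveaxis(gm @ mat, -1, axis))

        return Tensor._make(out, (a,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, bwd)


# -- 3-D convolution ----------------------------------------------------------

def _conv3d_cols(x: np.ndarray, kernel, stride, padding):
    """im2col for 3-D convolution.  Returns (cols, out_spatial).

    cols has shape (B, Do, Ho, Wo, C*kd*kh*kw).
    """
    kd, kh, kw = kernel
    sd, sh, sw = stride
    pd, ph, pw = padding
    xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    v = v[:, :, ::sd, ::sh, ::sw]  # B, C, Do, Ho, Wo, kd, kh, kw
    B, C, Do, Ho, Wo = v.shape[:5]
    cols = v.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(B, Do, Ho, Wo, C * kd * kh * kw)
    return np.ascontiguousarray(cols), (Do, Ho, Wo)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride=(1, 1, 1), padding=(0, 0, 0)) -> Tensor:
    """3-D cross-correlation: x (B,C,D,H,W) * w (O,C,kd,kh,kw) -> (B,O,Do,Ho,Wo)."""
    O, C, kd, kh, kw = w.shape
    B = x.shape[0]
    cols, (Do, Ho, Wo) = _conv3d_cols(x.data, (kd, kh, kw), stride, padding)
    wm = w.data.reshape(O, -1)
    out = cols.reshape(-1, cols.shape[-1]) @ wm.T  # (B*P, O)
    out = out.reshape(B, Do, Ho, Wo, O).transpose(0, 4, 1, 2, 3)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gm = g.transpose(0, 2, 3, 4, 1).reshape(-1, O)  # (B*P, O)
        if b is not None and b.requires_grad:
            b._accum(gm.sum(axis=0))
        if w.requires_grad:
            gw = gm.T @ cols.reshape(-1, cols.shape[-1])
            w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            dcols = (gm @ wm).reshape(B, Do, Ho, Wo, C, kd, kh, kw)
            sd, sh, sw = stride
            pd, ph, pw = padding
            Dp, Hp, Wp = x.shape[2] + 2 * pd, x.shape[3] + 2 * ph, x.shape[4] + 2 * pw
            dxp = np.zeros((B, C, Dp, Hp, Wp), dtype=g.dtype)
            for i in range(kd):
                for j in range(kh):
                    for k in range(kw):
                        dxp[:, :, i:i + sd * Do:sd, j:j + sh * Ho:sh, k:k + sw * Wo:sw] += \
                            dcols[:, :, :, :, :, i, j, k].transpose(0, 4, 1, 2, 3)
            x._accum(dxp[:, :, pd:Dp - pd, ph:Hp - ph, pw:Wp - pw])

    return Tensor._make(out, parents, bwd)
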