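"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Dynamic define-by-run graphs of :class:`Tensor` nodes, sufficient for small
volumetric encoder-decoder networks: 3D convolution (im2col + BLAS), nearest
upsampling, concatenation, pointwise activations, instance/batch
normalisation and the reductions needed by the training objectives.
Everything is deterministic given the inputs; there is no internal RNG.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "neg",
    "concat",
    "leaky_relu",
    "tanh",
    "sigmoid",
    "conv3d",
    "upsample_nearest2",
    "instance_norm",
    "batch_norm",
    "mean_all",
    "abs_mean",
    "sq_diff_mean",
    "bce_mean",
    "mean_sq_to_const",
]


class Tensor:
    """A NumPy array plus gradient bookkeeping.

    Gradients accumulate into ``.grad`` (same shape as ``.data``) on
    :meth:`backward`. Graph edges are stored as parent references plus a
    closure propagating the output gradient to each parent.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Small amount of operator sugar used by the layers/objectives code.
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


# ---------------------------------------------------------------------------
# elementwise arithmetic (shapes must match exactly, or one side scalar)
# ---------------------------------------------------------------------------

def _scalar_or_same(a: Tensor, b: Tensor) -> None:
    if a.data.shape != b.data.shape and a.data.ndim != 0 and b.data.ndim != 0:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")


def _reduce_to(g: np.ndarray, shape) -> np.ndarray:
    if g.shape == tuple(shape):
        return g
    return np.sum(g) if shape == () else g  # only scalar broadcasting allowed


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    _scalar_or_same(a, b)
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_reduce_to(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_reduce_to(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    _scalar_or_same(a, b)
    out_data = a.data - b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_reduce_to(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_reduce_to(-g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    _scalar_or_same(a, b)
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_reduce_to(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_reduce_to(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def neg(a) -> Tensor:
    a = as_tensor(a)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(-g)

    return Tensor(-a.data, parents=(a,), backward=bwd)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    x = as_tensor(x)
    pos = x.data > 0
    out_data = np.where(pos, x.data, slope * x.data)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.where(pos, g, slope * g))

    return Tensor(out_data, parents=(x,), backward=bwd)


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.tanh(x.data)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - out_data * out_data))

    return Tensor(out_data, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = 0.5 * (np.tanh(0.5 * x.data) + 1.0)  # numerically stable

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=bwd)


# ---------------------------------------------------------------------------
# 3D convolution (N, C, Z, Y, X) via im2col + batched matmul
# ---------------------------------------------------------------------------

def _pad5(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    n, c, z, y, xx = x.shape
    out = np.zeros((n, c, z + 2 * p, y + 2 * p, xx + 2 * p), dtype=x.dtype)
    out[:, :, p:p + z, p:p + y, p:p + xx] = x
    return out


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N,C,Zp,Yp,Xp) -> (N, C*k^3, P) column matrix, raster output order."""
    n, c = xp.shape[:2]
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k),
                                                   axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]  # (N,C,Zo,Yo,Xo,k,k,k)
    zo, yo, xo = win.shape[2:5]
    cols = win.transpose(0, 1, 5, 6, 7, 2, 3, 4).reshape(n, c * k**3,
                                                         zo * yo * xo)
    return np.ascontiguousarray(cols)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 1) -> Tensor:
    """3D cross-correlation. ``w``: (Cout, Cin, k, k, k); ``b``: (Cout,)."""
    x, w = as_tensor(x), as_tensor(w)
    n, cin = x.data.shape[:2]
    cout, cin_w, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    if cin != cin_w:
        raise ValueError(f"conv3d: input has {cin} channels, "
                         f"weight expects {cin_w}")
    xp = _pad5(x.data, padding)
    out_sp = tuple((s - k) // stride + 1 for s in xp.shape[2:])
    if min(out_sp) < 1:
        raise ValueError(f"conv3d: input spatial {x.data.shape[2:]} too small "
                         f"for kernel {k} stride {stride} pad {padding}")
    cols = _im2col(xp, k, stride)                      # (N, CK, P)
    wm = w.data.reshape(cout, -1)
    out = np.matmul(wm[None], cols)                    # (N, Cout, P)
    if b is not None:
        out = out + b.data[None, :, None]
    out_data = out.reshape(n, cout, *out_sp)

    def bwd(g):
        gm = g.reshape(n, cout, -1)                    # (N, Cout, P)
        if w.requires_grad:
            dw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gm.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(wm.T[None], gm)          # (N, CK, P)
            dcols = dcols.reshape(n, cin, k, k, k, *out_sp)
            dxp = np.zeros_like(xp)
            zo, yo, xo = out_sp
            for kz in range(k):
                for ky in range(k):
                    for kx in range(k):
                        dxp[:, :,
                            kz:kz + stride * zo:stride,
                            ky:ky + stride * yo:stride,
                            kx:kx + stride * xo:stride] += \
                            dcols[:, :, kz, ky, kx]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding,
                          padding:-padding]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=bwd)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling on the three spatial axes."""
    x = as_tensor(x)
    d = x.data
    out_data = d.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def bwd(g):
        if x.requires_grad:
            n, c, z, y, xx = d.shape
            gr = g.reshape(n, c, z, 2, y, 2, xx, 2).sum(axis=(3, 5, 7))
            x._accumulate(gr)

    return Tensor(out_data, parents=(x,), backward=bwd)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def _norm_over(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple,
               eps: float) -> Tensor:
    d = x.data
    mu = d.mean(axis=axes, keepdims=True)
    var = d.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (d - mu) * inv
    c_shape = [1] * d.ndim
    c_shape[1] = d.shape[1]
    gam = gamma.data.reshape(c_shape)
    out_data = xhat * gam + beta.data.reshape(c_shape)
    sum_axes = tuple(a for a in range(d.ndim) if a != 1)

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=sum_axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=sum_axes))
        if x.requires_grad:
            gx = g * gam  # d loss / d xhat
            t1 = gx
            t2 = gx.mean(axis=axes, keepdims=True)
            t3 = xhat * (gx * xhat).mean(axis=axes, keepdims=True)
            x._accumulate(inv * (t1 - t2 - t3))

    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over the spatial axes."""
    return _norm_over(x, gamma, beta, axes=(2, 3, 4), eps=eps)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Per-channel normalisation over batch and spatial axes (training mode)."""
    return _norm_over(x, gamma, beta, axes=(0, 2, 3, 4), eps=eps)


# ---------------------------------------------------------------------------
# reductions / losses
# ---------------------------------------------------------------------------

def mean_all(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n = x.data.size
    out_data = np.asarray(x.data.mean())

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / n, x.data.shape)
                          .astype(x.data.dtype))

    return Tensor(out_data, parents=(x,), backward=bwd)


def abs_mean(a: Tensor, b) -> Tensor:
    """mean |a - b| (mean absolute error)."""
    a = as_tensor(a)
    bd = b.data if isinstance(b, Tensor) else np.asarray(b)
    bt = b if isinstance(b, Tensor) else None
    diff = a.data - bd
    if a.data.shape != bd.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {bd.shape}")
    n = diff.size
    sign = np.sign(diff)
    out_data = np.asarray(np.abs(diff).mean())

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * sign / n)
        if bt is not None and bt.requires_grad:
            bt._accumulate(-g * sign / n)

    parents = (a,) if bt is None else (a, bt)
    return Tensor(out_data, parents=parents, backward=bwd)


def sq_diff_mean(a: Tensor, b) -> Tensor:
    """mean (a - b)^2 (mean squared error)."""
    a = as_tensor(a)
    bd = b.data if isinstance(b, Tensor) else np.asarray(b)
    bt = b if isinstance(b, Tensor) else None
    if a.data.shape != bd.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {bd.shape}")
    diff = a.data - bd
    n = diff.size
    out_data = np.asarray((diff * diff).mean())

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * 2.0 * diff / n)
        if bt is not None and bt.requires_grad:
            bt._accumulate(-g * 2.0 * diff / n)

    parents = (a,) if bt is None else (a, bt)
    return Tensor(out_data, parents=parents, backward=bwd)


def bce_mean(p: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy of probabilities ``p`` against a fixed
    binary target. Probabilities are clipped to [eps, 1-eps]; the gradient
    is zero where the clip is active."""
    p = as_tensor(p)
    t = np.asarray(target)
    if p.data.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.data.shape} vs {t.shape}")
    pc = np.clip(p.data, eps, 1.0 - eps)
    inside = (p.data > eps) & (p.data < 1.0 - eps)
    n = pc.size
    out_data = np.asarray(-(t * np.log(pc) + (1.0 - t) * np.log1p(-pc)).mean())

    def bwd(g):
        if p.requires_grad:
            dp = (-t / pc + (1.0 - t) / (1.0 - pc)) / n
            p._accumulate(g * np.where(inside, dp, 0.0))

    return Tensor(out_data, parents=(p,), backward=bwd)


def mean_sq_to_const(s: Tensor, c: float) -> Tensor:
    """mean (s - c)^2 against a scalar constant (LSGAN building block)."""
    s = as_tensor(s)
    diff = s.data - c
    n = diff.size
    out_data = np.asarray((diff * diff).mean())

    def bwd(g):
        if s.requires_grad:
            s._accumulate(g * 2.0 * diff / n)

    return Tensor(out_data, parents=(s,), backward=bwd)
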