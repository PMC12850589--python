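"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the segmentation networks need: N-D
convolution (stride 1, per-axis padding), transposed convolution with kernel
equal to stride, max pooling by integer factors, instance normalization,
ReLU/sigmoid, concatenation, reshape, and the elementwise/reduction algebra
required by the Dice and cross-entropy losses.  All gradients are verified
against central finite differences in the test suite.

Arrays are channels-first: ``(N, C, *spatial)``.  The graph is dynamic: each
op records its parents and a backward closure; ``Tensor.backward`` runs a
topological sweep.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _conv_jit

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "no_grad",
    "concat",
    "narrow",
    "conv_nd",
    "upconv_nd",
    "maxpool_nd",
    "instance_norm",
    "relu",
    "sigmoid",
    "log",
    "clip",
    "reshape",
    "tsum",
]

DTYPE = np.float32

_GRAD_ENABLED = True


class no_grad:
    """Context manager: ops create no graph inside (inference / validation)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        if not _GRAD_ENABLED and parents:
            parents, backward, requires_grad = (), None, False
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._parents)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # interior node: release the gradient, the closure (which may
                # capture large forward intermediates), and the graph links so
                # memory is reclaimed as the sweep proceeds
                node.grad = None
                node._backward = None
                node._parents = ()

    def _accum(self, g) -> None:
        g = np.asarray(g, dtype=DTYPE)
        self.grad = g if self.grad is None else self.grad + g

    # -- operator sugar (used mostly by the losses) --------------------------
    def __add__(self, other):
        return _elementwise_add(self, _as_tensor(other))

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        return _elementwise_mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return _elementwise_mul(self, _reciprocal(other))

    def __rtruediv__(self, other):
        return _as_tensor(other) / self


def tensor(data) -> Tensor:
    return Tensor(data)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to the shape it was broadcast from."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _elementwise_add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    return Tensor(out_data, (a, b), bwd)


def _elementwise_mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, (a, b), bwd)


def _reciprocal(a: Tensor) -> Tensor:
    out_data = 1.0 / a.data

    def bwd(g):
        if a.requires_grad:
            a._accum(-g * out_data * out_data)

    return Tensor(out_data, (a,), bwd)


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def bwd(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return Tensor(out_data, (a,), bwd)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    out_data = np.clip(a.data, lo, hi)
    inside = ((a.data > lo) & (a.data < hi)).astype(DTYPE)

    def bwd(g):
        if a.requires_grad:
            a._accum(g * inside)

    return Tensor(out_data, (a,), bwd)


def tsum(a: Tensor) -> Tensor:
    out_data = a.data.sum(dtype=np.float64).astype(DTYPE)

    def bwd(g):
        if a.requires_grad:
            a._accum(np.full(a.shape, g, dtype=DTYPE))

    return Tensor(out_data, (a,), bwd)


def relu(a: Tensor) -> Tensor:
    out_data = a.data * (a.data > 0)

    def bwd(g):
        if a.requires_grad:
            a._accum(g * (out_data > 0))

    return Tensor(out_data, (a,), bwd)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        if a.requires_grad:
            a._accum(g * out_data * (1.0 - out_data))

    return Tensor(out_data, (a,), bwd)


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def bwd(g):
        if a.requires_grad:
            a._accum(g.reshape(a.shape))

    return Tensor(out_data, (a,), bwd)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis (used to split weight-shared arm batches)."""
    sl = [slice(None)] * a.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    out_data = a.data[sl]

    def bwd(g):
        if a.requires_grad:
            full = np.zeros(a.shape, dtype=DTYPE)
            full[sl] = g
            a._accum(full)

    return Tensor(out_data, (a,), bwd)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, tuple(tensors), bwd)


def _resolve_padding(kernel, padding):
    """Per-spatial-axis (before, after) zero padding. 'same' assumes odd kernels."""
    if padding == "valid":
        return [(0, 0)] * len(kernel)
    if padding == "same":
        return [((k - 1) // 2, (k - 1) // 2) for k in kernel]
    return [tuple(p) for p in padding]


def _im2col(x: np.ndarray, kernel) -> tuple[np.ndarray, tuple[int, ...]]:
    """Unfold (N, Ci, *S) into the im2col matrix (N*P, Ci*prod(K)).

    One channels-last transpose and one large reshape-copy; the subsequent
    convolution is then a single GEMM running at BLAS speed.
    """
    d = len(kernel)
    n, ci = x.shape[:2]
    out_sp = tuple(s - k + 1 for s, k in zip(x.shape[2:], kernel))
    p = int(np.prod(out_sp))
    xt = np.ascontiguousarray(np.moveaxis(x, 1, -1))  # (N, *S, Ci)
    win = sliding_window_view(xt, kernel, axis=tuple(range(1, 1 + d)))  # (N,*O,Ci,*K)
    cols = win.reshape(n * p, ci * int(np.prod(kernel)))
    return cols, out_sp


def _raw_corr(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid cross-correlation, channels-first. x (N,Ci,*S), w (Co,Ci,*K) -> (N,Co,*O)."""
    if w.ndim - 2 == 3 and _conv_jit.use_jit(
        tuple(s - k + 1 for s, k in zip(x.shape[2:], w.shape[2:]))
    ):
        return _conv_jit.corr3d(x, w)
    kernel = w.shape[2:]
    n = x.shape[0]
    co = w.shape[0]
    cols, out_sp = _im2col(x, kernel)
    y = cols @ w.reshape(co, -1).T  # (N*P, Co)
    y = y.reshape((n,) + out_sp + (co,))
    return np.ascontiguousarray(np.moveaxis(y, -1, 1))


def _raw_corr_dw(x: np.ndarray, g: np.ndarray, kernel) -> np.ndarray:
    """Weight gradient of the valid cross-correlation: (Co, Ci, *K)."""
    if len(kernel) == 3 and _conv_jit.use_jit(g.shape[2:]):
        return _conv_jit.corr3d_dw(x, g, kernel)
    n, ci = x.shape[:2]
    co = g.shape[1]
    cols, out_sp = _im2col(x, kernel)
    gt = np.ascontiguousarray(np.moveaxis(g, 1, -1)).reshape(-1, co)
    dw = gt.T @ cols  # (Co, Ci*prod(K))
    return dw.reshape((co, ci) + tuple(kernel))


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None, padding="same") -> Tensor:
    """N-D convolution (cross-correlation), stride 1, zero padding."""
    d = w.data.ndim - 2
    kernel = w.data.shape[2:]
    pads = _resolve_padding(kernel, padding)
    xp = np.pad(x.data, [(0, 0), (0, 0)] + pads)
    out_data = _raw_corr(xp, w.data)
    if b is not None:
        out_data = out_data + b.data.reshape((1, -1) + (1,) * d)
    del xp  # re-padded on demand in backward; holding it would double memory

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, *range(2, 2 + d))))
        if w.requires_grad:
            xpb = np.pad(x.data, [(0, 0), (0, 0)] + pads)
            w._accum(_raw_corr_dw(xpb, g, kernel))
        if x.requires_grad:
            wf = np.flip(w.data, axis=tuple(range(2, 2 + d))).swapaxes(0, 1)
            gpads = [(k - 1 - pb, k - 1 - pa) for k, (pb, pa) in zip(kernel, pads)]
            gp = np.pad(g, [(0, 0), (0, 0)] + gpads)
            dx = _raw_corr(np.ascontiguousarray(gp), wf)
            x._accum(dx)

    return Tensor(out_data, tuple(t for t in (x, w, b) if t is not None), bwd)


def upconv_nd(x: Tensor, w: Tensor, b: Tensor | None, factors) -> Tensor:
    """Transposed convolution with kernel size equal to stride (learned upsampling).

    ``x``: (N, Ci, *S); ``w``: (Ci, Co, *F); output (N, Co, *(S*F)).
    """
    d = len(factors)
    n, ci = x.shape[:2]
    co = w.shape[1]
    s = x.shape[2:]
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # (N, *S, Co, *F)
    t = np.moveaxis(t, 1 + d, 1)  # (N, Co, *S, *F)
    # interleave: (N, Co, S1, F1, S2, F2, ...)
    order = [0, 1] + [2 + i + d * j for i in range(d) for j in (0, 1)]
    t = np.transpose(t, order)
    out_data = t.reshape((n, co) + tuple(si * fi for si, fi in zip(s, factors)))
    if b is not None:
        out_data = out_data + b.data.reshape((1, -1) + (1,) * d)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, *range(2, 2 + d))))
        # reshape gradient back into block form (N, Co, *S, *F)
        block_shape = (n, co) + tuple(v for si, fi in zip(s, factors) for v in (si, fi))
        gb = g.reshape(block_shape)
        inv = [0, 1] + [2 + 2 * i for i in range(d)] + [3 + 2 * i for i in range(d)]
        gb = np.transpose(gb, inv)  # (N, Co, *S, *F)
        if w.requires_grad:
            axes_x = [0] + list(range(2, 2 + d))
            axes_g = [0] + list(range(2, 2 + d))
            dw = np.tensordot(x.data, gb, axes=(axes_x, axes_g))  # (Ci, Co, *F)
            w._accum(dw)
        if x.requires_grad:
            axes_g = [1] + list(range(2 + d, 2 + 2 * d))
            axes_w = [1] + list(range(2, 2 + d))
            dx = np.tensordot(gb, w.data, axes=(axes_g, axes_w))  # (N, *S, Ci)
            x._accum(np.moveaxis(dx, -1, 1))

    return Tensor(out_data, tuple(t for t in (x, w, b) if t is not None), bwd)


def maxpool_nd(x: Tensor, factors) -> Tensor:
    """Max pooling by integer factors; spatial dims must be divisible."""
    d = len(factors)
    n, c = x.shape[:2]
    s = x.shape[2:]
    for si, fi in zip(s, factors):
        if si % fi:
            raise ValueError(f"spatial extent {si} not divisible by pool factor {fi}")
    out_sp = tuple(si // fi for si, fi in zip(s, factors))
    block_shape = (n, c) + tuple(v for si, fi in zip(s, factors) for v in (si // fi, fi))
    xb = x.data.reshape(block_shape)
    order = [0, 1] + [2 + 2 * i for i in range(d)] + [3 + 2 * i for i in range(d)]
    xb = np.transpose(xb, order).reshape((n, c) + out_sp + (-1,))
    arg = xb.argmax(axis=-1)
    out_data = np.take_along_axis(xb, arg[..., None], axis=-1)[..., 0]
    arg = arg.astype(np.uint8)  # pool factors are tiny; keep the cache small

    def bwd(g):
        if not x.requires_grad:
            return
        gb = np.zeros((n, c) + out_sp + (int(np.prod(factors)),), dtype=DTYPE)
        np.put_along_axis(gb, arg[..., None].astype(np.intp), g[..., None], axis=-1)
        gb = gb.reshape((n, c) + out_sp + tuple(factors))
        inv = np.argsort(order)
        gb = np.transpose(gb, inv).reshape(x.shape)
        x._accum(gb)

    return Tensor(out_data, (x,), bwd)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes, with affine."""
    d = x.data.ndim - 2
    axes = tuple(range(2, 2 + d))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    gshape = (1, -1) + (1,) * d
    out_data = gamma.data.reshape(gshape) * ((x.data - mu) * inv_std) + beta.data.reshape(gshape)

    def bwd(g):
        xhat = (x.data - mu) * inv_std  # recomputed; only mu/inv_std are kept
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, *axes)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, *axes)))
        if x.requires_grad:
            dxhat = g * gamma.data.reshape(gshape)
            term1 = dxhat
            term2 = dxhat.mean(axis=axes, keepdims=True)
            term3 = xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
            x._accum(inv_std * (term1 - term2 - term3))

    return Tensor(out_data, (x, gamma, beta), bwd)
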