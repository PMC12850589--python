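"""JIT-compiled direct 3D convolution kernels.

The spatio-temporal networks spend nearly all their time in stride-1 3D
convolutions.  At the full-resolution stages the channel counts are small
and an im2col + GEMM formulation is memory-bound on the gather, so those
layers use a direct convolution with a long unit-stride inner loop and the
output-channel loop unrolled four-wide (each input load feeds four FMA
chains).  Deep stages with tiny spatial extents but wide channels go the
other way: there the im2col matrix is small and BLAS wins, handled by the
GEMM path in ``autodiff`` (which is also the reference implementation and
the fallback when numba is unavailable).

Kernel layout (positional): inputs (N, S1, S2, Ci, S3) with the X axis —
the largest spatial extent in every training configuration — placed last;
weights (K1, K2, K3, Ci, Co); outputs (N, O1, O2, Co, O3).
"""

from __future__ import annotations

import numpy as np

try:
    import numba as nb

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is expected in practice
    HAVE_NUMBA = False

#: below this per-sample output voxel count the GEMM path is faster
MIN_JIT_POSITIONS = 4097


if HAVE_NUMBA:

    @nb.njit(fastmath=True, cache=True)
    def conv3d_fwd(x, w, y):
        """x (N,S1,S2,Ci,S3), w (K1,K2,K3,Ci,Co), y (N,O1,O2,Co,O3) overwritten."""
        n_, o1_, o2_, co_, o3_ = y.shape
        k1_, k2_, k3_, ci_, _ = w.shape
        a0 = np.empty(o3_, dtype=np.float32)
        a1 = np.empty(o3_, dtype=np.float32)
        a2 = np.empty(o3_, dtype=np.float32)
        a3 = np.empty(o3_, dtype=np.float32)
        co_quads = co_ - (co_ % 4)
        for n in range(n_):
            for o1 in range(o1_):
                for o2 in range(o2_):
                    for co in range(0, co_quads, 4):
                        for o3 in range(o3_):
                            a0[o3] = 0.0
                            a1[o3] = 0.0
                            a2[o3] = 0.0
                            a3[o3] = 0.0
                        for k1 in range(k1_):
                            for k2 in range(k2_):
                                for ci in range(ci_):
                                    for k3 in range(k3_):
                                        w0 = w[k1, k2, k3, ci, co]
                                        w1 = w[k1, k2, k3, ci, co + 1]
                                        w2 = w[k1, k2, k3, ci, co + 2]
                                        w3 = w[k1, k2, k3, ci, co + 3]
                                        for o3 in range(o3_):
                                            xv = x[n, o1 + k1, o2 + k2, ci, o3 + k3]
                                            a0[o3] += w0 * xv
                                            a1[o3] += w1 * xv
                                            a2[o3] += w2 * xv
                                            a3[o3] += w3 * xv
                        for o3 in range(o3_):
                            y[n, o1, o2, co, o3] = a0[o3]
                            y[n, o1, o2, co + 1, o3] = a1[o3]
                            y[n, o1, o2, co + 2, o3] = a2[o3]
                            y[n, o1, o2, co + 3, o3] = a3[o3]
                    for co in range(co_quads, co_):
                        for o3 in range(o3_):
                            a0[o3] = 0.0
                        for k1 in range(k1_):
                            for k2 in range(k2_):
                                for ci in range(ci_):
                                    for k3 in range(k3_):
                                        w0 = w[k1, k2, k3, ci, co]
                                        for o3 in range(o3_):
                                            a0[o3] += w0 * x[n, o1 + k1, o2 + k2, ci, o3 + k3]
                        for o3 in range(o3_):
                            y[n, o1, o2, co, o3] = a0[o3]

    @nb.njit(fastmath=True, cache=True)
    def conv3d_dw(x, g, dw):
        """x (N,S1,S2,Ci,S3), g (N,O1,O2,Co,O3), dw (K1,K2,K3,Ci,Co) zeroed."""
        n_, o1_, o2_, co_, o3_ = g.shape
        k1_, k2_, k3_, ci_, _ = dw.shape
        co_pairs = co_ - (co_ % 2)
        for n in range(n_):
            for o1 in range(o1_):
                for o2 in range(o2_):
                    for k1 in range(k1_):
                        for k2 in range(k2_):
                            for ci in range(ci_):
                                for k3 in range(k3_):
                                    for co in range(0, co_pairs, 2):
                                        acc0 = np.float32(0.0)
                                        acc1 = np.float32(0.0)
                                        for o3 in range(o3_):
                                            xv = x[n, o1 + k1, o2 + k2, ci, o3 + k3]
                                            acc0 += xv * g[n, o1, o2, co, o3]
                                            acc1 += xv * g[n, o1, o2, co + 1, o3]
                                        dw[k1, k2, k3, ci, co] += acc0
                                        dw[k1, k2, k3, ci, co + 1] += acc1
                                    for co in range(co_pairs, co_):
                                        acc0 = np.float32(0.0)
                                        for o3 in range(o3_):
                                            acc0 += (
                                                x[n, o1 + k1, o2 + k2, ci, o3 + k3]
                                                * g[n, o1, o2, co, o3]
                                            )
                                        dw[k1, k2, k3, ci, co] += acc0


# channels-first (N, C, X, Y, T) <-> jit layout (N, Y, T, C, X): X innermost
_X_IN = (0, 3, 4, 1, 2)
_X_OUT = (0, 3, 4, 1, 2)  # (N,OY,OT,Co,OX) -> (N,Co,OX,OY,OT)
_W_IN = (3, 4, 2, 1, 0)  # (Co,Ci,KX,KY,KT) -> (KY,KT,KX,Ci,Co)


def use_jit(out_sp) -> bool:
    return HAVE_NUMBA and int(np.prod(out_sp)) >= MIN_JIT_POSITIONS


def corr3d(x_cf: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid cross-correlation, channels-first API: x (N,Ci,*S), w (Co,Ci,*K)."""
    kernel = w.shape[2:]
    out_sp = tuple(s - k + 1 for s, k in zip(x_cf.shape[2:], kernel))
    xt = np.ascontiguousarray(np.transpose(x_cf, _X_IN))
    wt = np.ascontiguousarray(np.transpose(w, _W_IN))
    y = np.empty(
        (x_cf.shape[0], out_sp[1], out_sp[2], w.shape[0], out_sp[0]), dtype=np.float32
    )
    conv3d_fwd(xt, wt, y)
    return np.ascontiguousarray(np.transpose(y, _X_OUT))


def corr3d_dw(x_cf: np.ndarray, g_cf: np.ndarray, kernel) -> np.ndarray:
    """Weight gradient, channels-first API: returns (Co, Ci, *K)."""
    xt = np.ascontiguousarray(np.transpose(x_cf, _X_IN))
    gt = np.ascontiguousarray(np.transpose(g_cf, _X_IN))
    dw = np.zeros(
        (kernel[1], kernel[2], kernel[0], x_cf.shape[1], g_cf.shape[1]), dtype=np.float32
    )
    conv3d_dw(xt, gt, dw)
    # (KY,KT,KX,Ci,Co) -> (Co,Ci,KX,KY,KT)
    return np.ascontiguousarray(np.transpose(dw, (4, 3, 2, 0, 1)))
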