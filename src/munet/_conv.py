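"""Minimal 3-D convolutional network engine on numpy.

Whole-volume (no patching) 3-D convolution with stride 1 or 2, zero
padding, exact analytic backpropagation and an Adam optimizer — enough
to train the small networks in :mod:`munet.nets` on a single CPU. The
convolution is evaluated as a BLAS matrix product over im2col blocks;
gradients with respect to inputs use the matching col2im scatter-add,
so every layer passes a finite-difference gradient check (see the test
suite).

Performance notes (single core): the public :func:`conv3d` /
:func:`conv3d_backward` take channel-major ``(B, C, D, H, W)`` arrays.
Internally the training layers use a channels-last layout with a
numba-compiled im2col gather over a zero-padded flat canvas, which
turns the stride-1 convolution into a handful of large sgemm calls;
layers whose input never changes across epochs (the network's first
layer during training) can additionally cache their im2col matrix.
"""

from __future__ import annotations

import numba
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = ["conv3d", "conv3d_backward", "upsample2_linear", "upsample2_linear_adjoint",
           "ACTIVATIONS", "apply_activation", "activation_grad", "Adam"]

_CHUNK_FLOATS = 64_000_000  # im2col block budget (floats) -> ~256 MB per block


def _chunk_rows(B: int, Ho: int, Wo: int, cols: int) -> int:
    """Output-z slab thickness keeping the im2col block under budget."""
    return max(1, _CHUNK_FLOATS // max(1, B * Ho * Wo * cols))


def _out_size(n: int, s: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - s) // stride + 1


def _pad_same(s: int) -> int:
    return (s - 1) // 2


def conv3d(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int = 1):
    """y[k] = b_k + sum_i W[k,i] * x[i], zero padding, stride 1 or 2."""
    B, Cin, D, H, Wd = x.shape
    Cout, Cin_w, s, _, _ = W.shape
    if Cin != Cin_w:
        raise ValueError(f"input has {Cin} channels, kernels expect {Cin_w}")
    p = _pad_same(s)
    Do, Ho, Wo = (_out_size(n, s, stride, p) for n in (D, H, Wd))
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (s, s, s), axis=(2, 3, 4))[
        :, :, ::stride, ::stride, ::stride]  # (B, Cin, Do, Ho, Wo, s, s, s)
    Wmat = W.reshape(Cout, -1)  # (Cout, Cin*s^3)
    y = np.empty((B, Do, Ho, Wo, Cout), dtype=np.float32)
    zchunk = _chunk_rows(B, Ho, Wo, Cin * s ** 3)
    for z0 in range(0, Do, zchunk):
        z1 = min(Do, z0 + zchunk)
        blk = win[:, :, z0:z1]  # (B, Cin, dz, Ho, Wo, s,s,s)
        col = np.ascontiguousarray(blk.transpose(0, 2, 3, 4, 1, 5, 6, 7),
                                   dtype=np.float32).reshape(-1, Cin * s ** 3)
        y[:, z0:z1] = (col @ Wmat.T).reshape(B, z1 - z0, Ho, Wo, Cout)
    y += b.astype(np.float32)
    return np.ascontiguousarray(y.transpose(0, 4, 1, 2, 3))


def conv3d_backward(dy: np.ndarray, x: np.ndarray, W: np.ndarray, stride: int = 1,
                    need_dx: bool = True):
    """Gradients of :func:`conv3d`: returns (dx or None, dW, db)."""
    B, Cin, D, H, Wd = x.shape
    Cout, _, s, _, _ = W.shape
    p = _pad_same(s)
    Do, Ho, Wo = dy.shape[2:]
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (s, s, s), axis=(2, 3, 4))[
        :, :, ::stride, ::stride, ::stride]
    Wmat = W.reshape(Cout, -1)
    dW = np.zeros_like(Wmat, dtype=np.float32)
    db = dy.sum(axis=(0, 2, 3, 4)).astype(np.float32)
    dxp = np.zeros_like(xp, dtype=np.float32) if need_dx else None
    dyt = dy.transpose(0, 2, 3, 4, 1)  # (B, Do, Ho, Wo, Cout)
    zchunk = _chunk_rows(B, Ho, Wo, Cin * s ** 3)
    for z0 in range(0, Do, zchunk):
        z1 = min(Do, z0 + zchunk)
        blk = win[:, :, z0:z1]
        col = np.ascontiguousarray(blk.transpose(0, 2, 3, 4, 1, 5, 6, 7),
                                   dtype=np.float32).reshape(-1, Cin * s ** 3)
        dyblk = np.ascontiguousarray(dyt[:, z0:z1], dtype=np.float32).reshape(-1, Cout)
        dW += dyblk.T @ col
        if need_dx:
            dcol = (dyblk @ Wmat).reshape(B, z1 - z0, Ho, Wo, Cin, s, s, s)
            for a in range(s):
                for bb in range(s):
                    for c in range(s):
                        dxp[:, :,
                            a + z0 * stride: a + z1 * stride: stride,
                            bb: bb + Ho * stride: stride,
                            c: c + Wo * stride: stride] += \
                            dcol[..., a, bb, c].transpose(0, 4, 1, 2, 3)
    dx = None
    if need_dx:
        dx = dxp[:, :, p:p + D, p:p + H, p:p + Wd]
        dx = np.ascontiguousarray(dx)
    return dx, dW.reshape(W.shape), db


# ---------------------------------------------------------------------------
# fast channels-last stride-1 path (training hot loop)
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _gather_cols(canvas, offs, rowstart, P):  # pragma: no cover - numba
    """P[n, d*C:(d+1)*C] = canvas[rowstart[n] + offs[d], :]."""
    C = canvas.shape[1]
    for n in range(rowstart.shape[0]):
        base = rowstart[n]
        for d in range(offs.shape[0]):
            P[n, d * C:(d + 1) * C] = canvas[base + offs[d]]


@numba.njit(cache=True)
def _scatter_cols(dcanvas, offs, rowstart, dP):  # pragma: no cover - numba
    """Adjoint of :func:`_gather_cols` (scatter-add)."""
    C = dcanvas.shape[1]
    for n in range(rowstart.shape[0]):
        base = rowstart[n]
        for d in range(offs.shape[0]):
            dcanvas[base + offs[d]] += dP[n, d * C:(d + 1) * C]


def _canvas_layout(B, D, H, W, p):
    """Flat zero-padded canvas geometry and per-voxel canvas positions."""
    Dp, Hp, Wp = D + 2 * p, H + 2 * p, W + 2 * p
    z = np.arange(D) + p
    y = np.arange(H) + p
    x = np.arange(W) + p
    b = np.arange(B)
    pos = (((b[:, None, None, None] * Dp + z[None, :, None, None]) * Hp
            + y[None, None, :, None]) * Wp + x[None, None, None, :])
    return (Dp, Hp, Wp), pos.reshape(-1).astype(np.int64)


def _offsets(s, Hp, Wp):
    p = (s - 1) // 2
    d = np.arange(-p, p + 1)
    return (d[:, None, None] * (Hp * Wp) + d[None, :, None] * Wp
            + d[None, None, :]).reshape(-1).astype(np.int64)


class _FastConv1:
    """Stride-1 zero-padded conv on channels-last data.

    Work proceeds in row chunks (output voxels) so the im2col block
    stays within a fixed memory budget; with :meth:`enable_cache` the
    full column matrix of a fixed input is gathered once and reused
    across epochs (used for the first layer, whose input is the data).
    """

    def __init__(self):
        self._col_cache = None  # (data ptr, shape, s) -> P
        self._geom_cache = None  # canvas etc. of the last forward input

    def enable_cache(self):
        self._col_cache = {}

    def clear_cache(self):
        self._col_cache = None
        self._geom_cache = None

    _MAX_CACHED = 2  # training set + validation set

    def _full_cols(self, x_cl, s, canvas, rowstart, offs):
        key = (x_cl.ctypes.data, x_cl.shape, s)
        if key not in self._col_cache:
            C = x_cl.shape[-1]
            P = np.empty((rowstart.shape[0], s**3 * C), dtype=np.float32)
            _gather_cols(canvas, offs, rowstart, P)
            while len(self._col_cache) >= self._MAX_CACHED:
                self._col_cache.pop(next(iter(self._col_cache)))
            self._col_cache[key] = P
        return self._col_cache[key]

    def _geometry(self, x_cl, s):
        """Padded flat canvas of the input (reused between the forward and
        the immediately following backward on the same input)."""
        key = (x_cl.ctypes.data, x_cl.shape, s)
        if self._geom_cache is not None and self._geom_cache[0] == key:
            return self._geom_cache[1]
        B, D, H, W, C = x_cl.shape
        p = (s - 1) // 2
        (Dp, Hp, Wp), rowstart = _canvas_layout(B, D, H, W, p)
        canvas = np.zeros((B * Dp * Hp * Wp, C), dtype=np.float32)
        canvas.reshape(B, Dp, Hp, Wp, C)[:, p:p + D, p:p + H, p:p + W] = x_cl
        out = (p, (Dp, Hp, Wp), rowstart, canvas, _offsets(s, Hp, Wp))
        self._geom_cache = (key, out)
        return out

    def forward(self, x_cl, W, b):
        Cout, Cin, s, _, _ = W.shape
        B, D, H, Wd, C = x_cl.shape
        if C != Cin:
            raise ValueError(f"input has {C} channels, kernels expect {Cin}")
        p, (Dp, Hp, Wp), rowstart, canvas, offs = self._geometry(x_cl, s)
        nrows = rowstart.shape[0]
        cols = s**3 * Cin
        Wmat = np.ascontiguousarray(
            W.transpose(2, 3, 4, 1, 0).reshape(cols, Cout))
        y = np.empty((nrows, Cout), dtype=np.float32)
        if self._col_cache is not None:
            P = self._full_cols(x_cl, s, canvas, rowstart, offs)
            np.matmul(P, Wmat, out=y)
        else:
            step = max(1, _CHUNK_FLOATS // cols)
            buf = np.empty((min(step, nrows), cols), dtype=np.float32)
            for r0 in range(0, nrows, step):
                r1 = min(nrows, r0 + step)
                P = buf[: r1 - r0]
                _gather_cols(canvas, offs, rowstart[r0:r1], P)
                np.matmul(P, Wmat, out=y[r0:r1])
        y += b.astype(np.float32)
        return y.reshape(B, D, H, Wd, Cout)

    def backward(self, dy_cl, x_cl, W, need_dx=True):
        Cout, Cin, s, _, _ = W.shape
        B, D, H, Wd, C = x_cl.shape
        p, (Dp, Hp, Wp), rowstart, canvas, offs = self._geometry(x_cl, s)
        nrows = rowstart.shape[0]
        cols = s**3 * Cin
        dyf = dy_cl.reshape(-1, Cout)
        db = dyf.sum(axis=0)
        dx = None
        Wmat = np.ascontiguousarray(
            W.transpose(2, 3, 4, 1, 0).reshape(cols, Cout))
        # accumulate dW^T: (Cout, cols) gemms run markedly faster than (cols, Cout)
        dWmatT = np.zeros((Cout, cols), dtype=np.float32)
        dcanvas = np.zeros_like(canvas) if need_dx else None
        if self._col_cache is not None and not need_dx:
            P = self._full_cols(x_cl, s, canvas, rowstart, offs)
            dWmatT += dyf.T @ P
        else:
            step = max(1, _CHUNK_FLOATS // (2 * cols))
            buf = np.empty((min(step, nrows), cols), dtype=np.float32)
            for r0 in range(0, nrows, step):
                r1 = min(nrows, r0 + step)
                P = buf[: r1 - r0]
                _gather_cols(canvas, offs, rowstart[r0:r1], P)
                dWmatT += dyf[r0:r1].T @ P
                if need_dx:
                    dP = dyf[r0:r1] @ Wmat.T
                    _scatter_cols(dcanvas, offs, rowstart[r0:r1], dP)
        dW = np.ascontiguousarray(
            dWmatT.T.reshape(s, s, s, Cin, Cout).transpose(4, 3, 0, 1, 2))
        if need_dx:
            dx = np.ascontiguousarray(
                dcanvas.reshape(B, Dp, Hp, Wp, Cin)[:, p:p + D, p:p + H, p:p + Wd])
        return dx, dW, db


def _cols_stride2(x_cl, s):
    """Channels-last im2col with stride 2 (output voxel counts are small)."""
    B, D, H, W, C = x_cl.shape
    p = (s - 1) // 2
    xp = np.pad(x_cl, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (s, s, s), axis=(1, 2, 3))[:, ::2, ::2, ::2]
    # win: (B, Do, Ho, Wo, C, s, s, s) -> rows (b,z,y,x), cols (dz,dy,dx,c)
    Do, Ho, Wo = win.shape[1:4]
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 3, 5, 6, 7, 4),
                                dtype=np.float32).reshape(-1, s**3 * C)
    return cols, (Do, Ho, Wo)


def _conv_cl_stride2(x_cl, W, b):
    Cout, Cin, s = W.shape[:3]
    Wmat = np.ascontiguousarray(W.transpose(2, 3, 4, 1, 0).reshape(-1, Cout))
    cols, (Do, Ho, Wo) = _cols_stride2(x_cl, s)
    y = cols @ Wmat
    y += b.astype(np.float32)
    return y.reshape(x_cl.shape[0], Do, Ho, Wo, Cout)


def _conv_cl_stride2_backward(dy_cl, x_cl, W, need_dx=True):
    Cout, Cin, s = W.shape[:3]
    B, D, H, Wd, _ = x_cl.shape
    cols, (Do, Ho, Wo) = _cols_stride2(x_cl, s)
    dyf = dy_cl.reshape(-1, Cout)
    dWmat = cols.T @ dyf
    dW = np.ascontiguousarray(
        dWmat.reshape(s, s, s, Cin, Cout).transpose(4, 3, 0, 1, 2))
    db = dyf.sum(axis=0)
    dx = None
    if need_dx:
        Wmat = np.ascontiguousarray(W.transpose(2, 3, 4, 1, 0).reshape(-1, Cout))
        dcols = (dyf @ Wmat.T).reshape(B, Do, Ho, Wo, s, s, s, Cin)
        p = (s - 1) // 2
        dxp = np.zeros((B, D + 2 * p, H + 2 * p, Wd + 2 * p, Cin), dtype=np.float32)
        for a in range(s):
            for bb in range(s):
                for c in range(s):
                    dxp[:, a:a + Do * 2:2, bb:bb + Ho * 2:2, c:c + Wo * 2:2] += \
                        dcols[:, :, :, :, a, bb, c]
        dx = np.ascontiguousarray(dxp[:, p:p + D, p:p + H, p:p + Wd])
    return dx, dW, db


def _up1(x: np.ndarray, axis: int) -> np.ndarray:
    """Double an axis by linear interpolation (cell-centered, edges clamped)."""
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    out = np.empty(x.shape[:-1] + (2 * n,), dtype=x.dtype)
    out[..., 0::2] = 0.75 * x
    out[..., 1::2] = 0.75 * x
    out[..., 2::2] += 0.25 * x[..., :-1]
    out[..., 0] += 0.25 * x[..., 0]
    out[..., 1:-1:2] += 0.25 * x[..., 1:]
    out[..., -1] += 0.25 * x[..., -1]
    return np.moveaxis(out, -1, axis)


def _up1_adj(y: np.ndarray, axis: int) -> np.ndarray:
    """Exact adjoint of :func:`_up1`."""
    y = np.moveaxis(y, axis, -1)
    n = y.shape[-1] // 2
    x = 0.75 * (y[..., 0::2] + y[..., 1::2])
    x[..., :-1] += 0.25 * y[..., 2::2]
    x[..., 0] += 0.25 * y[..., 0]
    x[..., 1:] += 0.25 * y[..., 1:-1:2]
    x[..., -1] += 0.25 * y[..., -1]
    return np.moveaxis(x, -1, axis)


def upsample2_linear(x: np.ndarray, axes=(2, 3, 4)) -> np.ndarray:
    """Trilinear x2 upsampling along the given (spatial) axes."""
    for ax in axes:
        x = _up1(x, ax)
    return np.ascontiguousarray(x, dtype=np.float32)


def upsample2_linear_adjoint(dy: np.ndarray, axes=(2, 3, 4)) -> np.ndarray:
    for ax in axes:
        dy = _up1_adj(dy, ax)
    return np.ascontiguousarray(dy, dtype=np.float32)


def apply_activation(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return expit(z)
    if kind == "elu":
        return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0))).astype(z.dtype)
    if kind == "linear":
        return z
    raise ValueError(f"unknown activation {kind!r}")


def activation_grad(a: np.ndarray, z: np.ndarray, kind: str) -> np.ndarray:
    """d activation / d z, expressed via the cached output ``a``."""
    if kind == "sigmoid":
        return a * (1.0 - a)
    if kind == "elu":
        return np.where(z > 0, np.float32(1.0), a + np.float32(1.0))
    if kind == "linear":
        return np.ones_like(a)
    raise ValueError(f"unknown activation {kind!r}")


ACTIVATIONS = ("sigmoid", "elu", "linear")


class Adam:
    """Adaptive-moment gradient descent over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
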