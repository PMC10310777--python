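"""Low-level 3D convolution primitives (forward and gradients).

Everything operates on unbatched, channels-first ``float32`` tensors of
shape ``(C, D, H, W)``; kernels are ``(C_out, C_in, kd, kh, kw)``.  Two
complementary GEMM formulations are used:

* *im2col*: materialize sliding windows and contract with the kernel —
  cheapest when ``C_in * k^3`` is small (e.g. the single-channel encoder).
* *shift-GEMM*: one GEMM ``(C_out*K, C_in) @ (C_in, P)`` over the padded
  input followed by ``K`` strided slab additions — cheapest when ``C_out``
  is small and avoids the im2col copy entirely.

The backward pass is uniform for every stride: scatter the output gradient
into a ``(C_out*K, P)`` buffer ``dz`` aligned with the padded input, then
``dX = W^T dz`` and ``dW = dz X^T`` are two GEMMs.  Transposed convolution
reuses the same buffers with the roles of gather and scatter swapped.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv3d_forward",
    "conv3d_backward",
    "conv_transpose3d_forward",
    "conv_transpose3d_backward",
    "reflection_pad3d",
    "reflection_pad3d_backward",
]

F32 = np.float32


def _pad_zeros(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))


def reflection_pad3d(x: np.ndarray, pad: int) -> np.ndarray:
    """Reflect-pad the three spatial axes of a ``(C, D, H, W)`` tensor."""
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)), mode="reflect")


def reflection_pad3d_backward(dyp: np.ndarray, pad: int) -> np.ndarray:
    """Fold gradients of a reflect-padded tensor back onto the core grid."""
    if pad == 0:
        return dyp
    g = dyp
    for ax in (1, 2, 3):
        gm = np.moveaxis(g, ax, 1)
        n = gm.shape[1] - 2 * pad
        core = gm[:, pad : pad + n].copy()
        for j in range(pad):
            core[:, pad - j] += gm[:, j]  # padded[j] mirrors x[pad - j]
            core[:, n - 2 - j] += gm[:, pad + n + j]
        g = np.moveaxis(core, 1, ax)
    return np.ascontiguousarray(g)


def _out_size(n: int, k: int, stride: int) -> int:
    return (n - k) // stride + 1


def conv3d_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray | None, stride: int = 1, pad: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Valid cross-correlation of the zero-padded input.

    Returns ``(y, x_padded)``; the padded input is cached for the backward
    pass.
    """
    co, ci, kd, kh, kw = w.shape
    xp = np.ascontiguousarray(_pad_zeros(x, pad), dtype=F32)
    D, H, W = xp.shape[1:]
    do, ho, wo = _out_size(D, kd, stride), _out_size(H, kh, stride), _out_size(W, kw, stride)
    if min(do, ho, wo) < 1:
        raise ValueError(f"input spatial shape {x.shape[1:]} too small for kernel {w.shape[2:]}")

    if ci * kd * kh * kw <= co * kd * kh * kw:  # im2col when C_in <= C_out
        win = sliding_window_view(xp, (kd, kh, kw), axis=(1, 2, 3))
        win = win[:, ::stride, ::stride, ::stride]
        cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(do * ho * wo, ci * kd * kh * kw)
        y = cols @ w.reshape(co, -1).T.astype(F32)
        y = np.ascontiguousarray(y.T.reshape(co, do, ho, wo))
    else:
        k3 = kd * kh * kw
        wz = np.ascontiguousarray(w.transpose(0, 2, 3, 4, 1).reshape(co * k3, ci), dtype=F32)
        z = (wz @ xp.reshape(ci, D * H * W)).reshape(co, kd, kh, kw, D, H, W)
        y = np.zeros((co, do, ho, wo), dtype=F32)
        for a, bb, g in itertools.product(range(kd), range(kh), range(kw)):
            y += z[
                :,
                a,
                bb,
                g,
                a : a + stride * (do - 1) + 1 : stride,
                bb : bb + stride * (ho - 1) + 1 : stride,
                g : g + stride * (wo - 1) + 1 : stride,
            ]
    if b is not None:
        y += b.reshape(co, 1, 1, 1)
    return y, xp


def _scatter_dz(dy: np.ndarray, kshape: tuple[int, int, int], pshape: tuple[int, int, int], stride: int) -> np.ndarray:
    """Spread ``dy`` over the padded-input grid, one slab per kernel tap."""
    co, do, ho, wo = dy.shape
    kd, kh, kw = kshape
    D, H, W = pshape
    dz = np.zeros((co, kd, kh, kw, D, H, W), dtype=F32)
    for a, bb, g in itertools.product(range(kd), range(kh), range(kw)):
        dz[
            :,
            a,
            bb,
            g,
            a : a + stride * (do - 1) + 1 : stride,
            bb : bb + stride * (ho - 1) + 1 : stride,
            g : g + stride * (wo - 1) + 1 : stride,
        ] = dy
    return dz


def conv3d_backward(
    dy: np.ndarray,
    xp: np.ndarray,
    w: np.ndarray,
    stride: int = 1,
    pad: int = 0,
    need_dx: bool = True,
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Gradients of :func:`conv3d_forward`; returns ``(dx, dw, db)``.

    Two equivalent GEMM formulations with buffers proportional to
    ``C_out * K`` (scatter) or ``C_in * K`` (gather); the cheaper one is
    chosen per layer.
    """
    co, ci, kd, kh, kw = w.shape
    db = dy.sum(axis=(1, 2, 3)).astype(F32)
    if co <= ci:
        dx, dw = _backward_scatter(dy, xp, w, stride, need_dx)
    else:
        dx, dw = _backward_gather(dy, xp, w, stride, need_dx)
    if need_dx and pad > 0:
        dx = np.ascontiguousarray(dx[:, pad:-pad, pad:-pad, pad:-pad])
    return dx, dw, db


def _backward_scatter(dy, xp, w, stride, need_dx):
    co, ci, kd, kh, kw = w.shape
    D, H, W = xp.shape[1:]
    k3 = kd * kh * kw
    dz = _scatter_dz(np.asarray(dy, dtype=F32), (kd, kh, kw), (D, H, W), stride)
    dz_flat = dz.reshape(co * k3, D * H * W)
    dw = (dz_flat @ xp.reshape(ci, -1).T).reshape(co, kd, kh, kw, ci).transpose(0, 4, 1, 2, 3)
    dx = None
    if need_dx:
        wz = np.ascontiguousarray(w.transpose(0, 2, 3, 4, 1).reshape(co * k3, ci), dtype=F32)
        dx = (wz.T @ dz_flat).reshape(ci, D, H, W)
    return dx, np.ascontiguousarray(dw)


def _backward_gather(dy, xp, w, stride, need_dx):
    co, ci, kd, kh, kw = w.shape
    D, H, W = xp.shape[1:]
    k3 = kd * kh * kw
    do, ho, wo = dy.shape[1:]
    m = do * ho * wo
    dyf = np.ascontiguousarray(dy, dtype=F32).reshape(co, m)
    # gather shifted input slabs, one per kernel tap
    xs = np.empty((kd, kh, kw, ci, m), dtype=F32)
    taps = []
    for a, bb, g in itertools.product(range(kd), range(kh), range(kw)):
        sl = (
            slice(a, a + stride * (do - 1) + 1, stride),
            slice(bb, bb + stride * (ho - 1) + 1, stride),
            slice(g, g + stride * (wo - 1) + 1, stride),
        )
        taps.append((a, bb, g, sl))
        xs[a, bb, g] = xp[:, sl[0], sl[1], sl[2]].reshape(ci, m)
    dw = (dyf @ xs.reshape(k3 * ci, m).T).reshape(co, kd, kh, kw, ci).transpose(0, 4, 1, 2, 3)
    dx = None
    if need_dx:
        wt = np.ascontiguousarray(w.transpose(2, 3, 4, 1, 0).reshape(k3 * ci, co), dtype=F32)
        t = (wt @ dyf).reshape(kd, kh, kw, ci, do, ho, wo)
        dx = np.zeros((ci, D, H, W), dtype=F32)
        for a, bb, g, sl in taps:
            dx[:, sl[0], sl[1], sl[2]] += t[a, bb, g]
    return dx, np.ascontiguousarray(dw)


def _transpose_geometry(n_in: int, k: int, stride: int, pad: int, opad: int) -> int:
    return (n_in - 1) * stride - 2 * pad + k + opad


def conv_transpose3d_forward(
    x: np.ndarray,
    w: np.ndarray,
    b: np.ndarray | None,
    stride: int = 2,
    pad: int = 1,
    opad: int = 1,
) -> np.ndarray:
    """Transposed convolution; ``w`` has shape ``(C_in, C_out, kd, kh, kw)``.

    ``y[o, q] = sum_{c,p,k} x[c, p] w[c, o, k]`` over ``q = stride*p - pad + k``.
    """
    ci, co, kd, kh, kw = w.shape
    _, D, H, W = x.shape
    od = _transpose_geometry(D, kd, stride, pad, opad)
    oh = _transpose_geometry(H, kh, stride, pad, opad)
    ow = _transpose_geometry(W, kw, stride, pad, opad)
    k3 = kd * kh * kw
    wz = np.ascontiguousarray(w.transpose(1, 2, 3, 4, 0).reshape(co * k3, ci), dtype=F32)
    z = (wz @ np.ascontiguousarray(x, dtype=F32).reshape(ci, -1)).reshape(co, kd, kh, kw, D, H, W)
    y = np.zeros((co, od, oh, ow), dtype=F32)
    for a, bb, g in itertools.product(range(kd), range(kh), range(kw)):
        sl = []
        src = []
        ok = True
        for tap, n_in, n_out in ((a, D, od), (bb, H, oh), (g, W, ow)):
            # valid p range: 0 <= stride*p - pad + tap <= n_out - 1
            p0 = max(0, -(-(pad - tap) // stride))  # ceil((pad - tap)/stride)
            p1 = min(n_in - 1, (n_out - 1 + pad - tap) // stride)
            if p0 > p1:
                ok = False
                break
            q0 = stride * p0 - pad + tap
            sl.append(slice(q0, q0 + stride * (p1 - p0) + 1, stride))
            src.append(slice(p0, p1 + 1))
        if not ok:
            continue
        y[:, sl[0], sl[1], sl[2]] += z[:, a, bb, g, src[0], src[1], src[2]]
    if b is not None:
        y += b.reshape(co, 1, 1, 1)
    return y


def conv_transpose3d_backward(
    dy: np.ndarray,
    x: np.ndarray,
    w: np.ndarray,
    stride: int = 2,
    pad: int = 1,
    opad: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`conv_transpose3d_forward`; returns ``(dx, dw, db)``."""
    ci, co, kd, kh, kw = w.shape
    _, D, H, W = x.shape
    od, oh, ow = dy.shape[1:]
    k3 = kd * kh * kw
    # gather dy back onto the input grid, one slab per tap
    dzg = np.zeros((co, kd, kh, kw, D, H, W), dtype=F32)
    dyf = np.asarray(dy, dtype=F32)
    for a, bb, g in itertools.product(range(kd), range(kh), range(kw)):
        sl = []
        src = []
        ok = True
        for tap, n_in, n_out in ((a, D, od), (bb, H, oh), (g, W, ow)):
            p0 = max(0, -(-(pad - tap) // stride))
            p1 = min(n_in - 1, (n_out - 1 + pad - tap) // stride)
            if p0 > p1:
                ok = False
                break
            q0 = stride * p0 - pad + tap
            sl.append(slice(q0, q0 + stride * (p1 - p0) + 1, stride))
            src.append(slice(p0, p1 + 1))
        if not ok:
            continue
        dzg[:, a, bb, g, src[0], src[1], src[2]] = dyf[:, sl[0], sl[1], sl[2]]
    dzg_flat = dzg.reshape(co * k3, D * H * W)
    wz = w.transpose(1, 2, 3, 4, 0).reshape(co * k3, ci).astype(F32)
    dx = (wz.T @ dzg_flat).reshape(ci, D, H, W)
    xf = np.ascontiguousarray(x, dtype=F32).reshape(ci, -1)
    dw = (xf @ dzg_flat.T).reshape(ci, co, kd, kh, kw)
    db = dyf.sum(axis=(1, 2, 3))
    return np.ascontiguousarray(dx), np.ascontiguousarray(dw), db
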