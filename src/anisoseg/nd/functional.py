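"""Differentiable operations for the ``anisoseg.nd`` engine.

Every function takes and returns :class:`~anisoseg.nd.tensor.Tensor` and
registers a backward closure.  Convolutions use an im2col / col2im
formulation so the heavy lifting is a single BLAS matmul; transposed
convolution is restricted to kernel == stride (the only case the decoders
need), where it reduces to a tensordot plus a block reshape.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .tensor import DTYPE, Tensor, unbroadcast

Triple = Tuple[int, int, int]


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a.accumulate(unbroadcast(g, a.data.shape))
        b.accumulate(unbroadcast(g, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        a.accumulate(unbroadcast(g * b.data, a.data.shape))
        b.accumulate(unbroadcast(g * a.data, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    out_data = a.data * DTYPE(c)

    def backward(g):
        a.accumulate(g * DTYPE(c))

    return Tensor._make(out_data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a.accumulate(unbroadcast(ga, a.data.shape))
        b.accumulate(unbroadcast(gb, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def reshape(x: Tensor, shape: Tuple[int, ...]) -> Tensor:
    in_shape = x.data.shape
    out_data = x.data.reshape(shape)

    def backward(g):
        x.accumulate(g.reshape(in_shape))

    return Tensor._make(out_data, (x,), backward)


def transpose(x: Tensor, axes: Tuple[int, ...]) -> Tensor:
    out_data = np.ascontiguousarray(x.data.transpose(axes))
    inv = np.argsort(axes)

    def backward(g):
        x.accumulate(g.transpose(inv))

    return Tensor._make(out_data, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t.accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def sum_(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = x.data.sum(axis=axis, keepdims=keepdims, dtype=DTYPE)

    def backward(g):
        if axis is None:
            x.accumulate(np.broadcast_to(g, x.data.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        x.accumulate(np.broadcast_to(g, x.data.shape))

    return Tensor._make(out_data, (x,), backward)


def mean_(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = x.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([x.data.shape[a] for a in axes]))
    return scale(sum_(x, axis=axis, keepdims=keepdims), 1.0 / n)


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    fac = np.where(x.data > 0, DTYPE(1.0), DTYPE(slope))
    out_data = x.data * fac

    def backward(g):
        x.accumulate(g * fac)

    return Tensor._make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data, dtype=DTYPE))

    def backward(g):
        x.accumulate(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted, dtype=DTYPE)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x.accumulate(out_data * (g - dot))

    return Tensor._make(out_data, (x,), backward)


def clipped_log(x: Tensor, eps: float = 1e-7) -> Tensor:
    """log(clip(x, eps, None)); gradient is zero where the clip is active."""
    clipped = np.clip(x.data, eps, None)
    out_data = np.log(clipped, dtype=DTYPE)
    active = x.data >= eps

    def backward(g):
        x.accumulate(np.where(active, g / clipped, 0.0).astype(DTYPE))

    return Tensor._make(out_data, (x,), backward)


def linear(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None) -> Tensor:
    """x @ W.T + b with W of shape (out_features, in_features)."""
    out_data = x.data @ weight.data.T
    if bias is not None:
        out_data = out_data + bias.data

    def backward(g):
        x.accumulate(g @ weight.data)
        gw = np.tensordot(g, x.data, axes=(range(g.ndim - 1), range(g.ndim - 1)))
        weight.accumulate(gw)
        if bias is not None:
            bias.accumulate(g.sum(axis=tuple(range(g.ndim - 1))))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

def _offset_view(xp: np.ndarray, i: int, j: int, l: int,
                 out_dims: Triple, stride: Triple) -> np.ndarray:
    do, ho, wo = out_dims
    sd, sh, sw = stride
    return xp[:, :, i:i + sd * do:sd, j:j + sh * ho:sh, l:l + sw * wo:sw]


def conv3d(x: Tensor, weight: Tensor, bias: Optional[Tensor],
           stride: Triple = (1, 1, 1), padding: Triple = (0, 0, 0)) -> Tensor:
    """Cross-correlation of (N,Ci,D,H,W) with (Co,Ci,kd,kh,kw).

    Computed as a sum over kernel offsets of pointwise (Co,Ci) matmuls on
    shifted views of the padded input: one small GEMM per kernel tap,
    which avoids materializing an im2col patch matrix.
    """
    n, ci, d, h, w = x.data.shape
    co, ci_w, kd, kh, kw = weight.data.shape
    if ci != ci_w:
        raise ValueError(f"conv3d channel mismatch: input {ci}, weight {ci_w}")
    pd, ph, pw = padding
    sd, sh, sw = stride
    do = (d + 2 * pd - kd) // sd + 1
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    if any(p > 0 for p in padding):
        xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    else:
        xp = x.data
    p_out = do * ho * wo
    out_mat = np.zeros((n, co, p_out), dtype=DTYPE)
    buf = np.empty((n, ci, do, ho, wo), dtype=DTYPE)
    for i in range(kd):
        for j in range(kh):
            for l in range(kw):
                np.copyto(buf, _offset_view(xp, i, j, l, (do, ho, wo), stride))
                out_mat += weight.data[:, :, i, j, l] @ buf.reshape(n, ci, p_out)
    out = out_mat.reshape(n, co, do, ho, wo)
    if bias is not None:
        out += bias.data[None, :, None, None, None]

    def backward(g):
        gmat = g.reshape(n, co, p_out)
        if bias is not None:
            bias.accumulate(g.sum(axis=(0, 2, 3, 4)))
        dw = np.empty_like(weight.data)
        bufb = np.empty((n, ci, do, ho, wo), dtype=DTYPE)
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for i in range(kd):
            for j in range(kh):
                for l in range(kw):
                    np.copyto(bufb, _offset_view(xp, i, j, l, (do, ho, wo), stride))
                    xs = bufb.reshape(n, ci, p_out)
                    dw[:, :, i, j, l] = np.matmul(gmat, xs.transpose(0, 2, 1)).sum(axis=0)
                    if dxp is not None:
                        contrib = weight.data[:, :, i, j, l].T @ gmat  # (N,Ci,P)
                        _offset_view(dxp, i, j, l, (do, ho, wo), stride)[...] += \
                            contrib.reshape(n, ci, do, ho, wo)
        weight.accumulate(dw)
        if dxp is not None:
            if any(p > 0 for p in padding):
                x.accumulate(dxp[:, :, pd:pd + d, ph:ph + h, pw:pw + w])
            else:
                x.accumulate(dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, backward)


def conv_transpose3d(x: Tensor, weight: Tensor, bias: Optional[Tensor],
                     factor: Triple) -> Tensor:
    """Transposed convolution with kernel == stride == ``factor`` (no overlap).

    weight has shape (Ci, Co, kd, kh, kw); each input voxel paints one
    kd x kh x kw output block, so upsampling is an exact block expansion.
    """
    n, ci, d, h, w = x.data.shape
    ci_w, co, kd, kh, kw = weight.data.shape
    if ci != ci_w:
        raise ValueError(f"conv_transpose3d channel mismatch: input {ci}, weight {ci_w}")
    if (kd, kh, kw) != tuple(factor):
        raise ValueError("conv_transpose3d requires kernel == stride")
    t = np.tensordot(x.data, weight.data, axes=([1], [0]))  # (N,D,H,W,Co,kd,kh,kw)
    t = t.transpose(0, 4, 1, 5, 2, 6, 3, 7)  # (N,Co,D,kd,H,kh,W,kw)
    out = np.ascontiguousarray(t).reshape(n, co, d * kd, h * kh, w * kw)
    if bias is not None:
        out = out + bias.data[None, :, None, None, None]

    def backward(g):
        gb = g.reshape(n, co, d, kd, h, kh, w, kw).transpose(0, 2, 4, 6, 1, 3, 5, 7)
        # gb: (N,D,H,W,Co,kd,kh,kw)
        weight.accumulate(np.tensordot(x.data, gb, axes=([0, 2, 3, 4], [0, 1, 2, 3])))
        if bias is not None:
            bias.accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            dx = np.tensordot(gb, weight.data, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
            x.accumulate(dx.transpose(0, 4, 1, 2, 3))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, backward)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch norm over (N, D, H, W) for a (N,C,D,H,W) input.

    ``running_mean`` / ``running_var`` are plain arrays updated in place in
    training mode and used verbatim in eval mode.
    """
    axes = (0, 2, 3, 4)
    if training:
        m = x.data.mean(axis=axes, dtype=np.float64)
        var = x.data.var(axis=axes, dtype=np.float64)
        running_mean += momentum * (m - running_mean)
        running_var += momentum * (var - running_var)
    else:
        m, var = running_mean, running_var
    m = m.astype(DTYPE)
    inv_std = (1.0 / np.sqrt(var + eps)).astype(DTYPE)
    xhat = (x.data - m[None, :, None, None, None]) * inv_std[None, :, None, None, None]
    out = gamma.data[None, :, None, None, None] * xhat + beta.data[None, :, None, None, None]

    nred = x.data.shape[0] * x.data.shape[2] * x.data.shape[3] * x.data.shape[4]

    def backward(g):
        gamma.accumulate((g * xhat).sum(axis=axes))
        beta.accumulate(g.sum(axis=axes))
        if not x.requires_grad:
            return
        gxh = g * gamma.data[None, :, None, None, None]
        if training:
            s1 = gxh.sum(axis=axes, keepdims=True)
            s2 = (gxh * xhat).sum(axis=axes, keepdims=True)
            dx = (gxh - s1 / nred - xhat * s2 / nred) * inv_std[None, :, None, None, None]
        else:
            dx = gxh * inv_std[None, :, None, None, None]
        x.accumulate(dx.astype(DTYPE))

    return Tensor._make(out, (x, gamma, beta), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis (per token, over channels)."""
    m = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - m) * inv_std
    out = gamma.data * xhat + beta.data
    nred = x.data.shape[-1]
    red = tuple(range(x.data.ndim - 1))

    def backward(g):
        gamma.accumulate((g * xhat).sum(axis=red))
        beta.accumulate(g.sum(axis=red))
        if not x.requires_grad:
            return
        gxh = g * gamma.data
        s1 = gxh.sum(axis=-1, keepdims=True)
        s2 = (gxh * xhat).sum(axis=-1, keepdims=True)
        x.accumulate(((gxh - s1 / nred - xhat * s2 / nred) * inv_std).astype(DTYPE))

    return Tensor._make(out, (x, gamma, beta), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,D,H,W) -> (N,C): mean over the spatial extent."""
    return mean_(x, axis=(2, 3, 4))
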