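"""Differentiable operations for the segmentation network.

Every function takes and returns :class:`~ridgeseg.nn.tensor.Tensor` objects
and registers a backward closure on the output. Convolutions use stride 1
(downsampling is done by max pooling, upsampling by bilinear interpolation
or a 2x transposed convolution), which keeps the implementations short and
the memory footprint small: convolution is computed as a sum over kernel
taps, each tap a (C_in -> C_out) contraction on a shifted view of the padded
input, so no im2col buffer is materialised.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = [
    "add",
    "mul",
    "relu",
    "sigmoid",
    "conv2d",
    "conv_transpose2d_2x",
    "max_pool2d",
    "upsample_bilinear",
    "concat",
    "mean_axis",
    "sum_all",
    "batch_norm",
    "cross_entropy_with_logits",
]


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, a.requires_grad or b.requires_grad, (a, b))

    def _bw():
        a.accumulate(_unbroadcast(out.grad, a.shape))
        b.accumulate(_unbroadcast(out.grad, b.shape))

    out._backward = _bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, a.requires_grad or b.requires_grad, (a, b))

    def _bw():
        a.accumulate(_unbroadcast(out.grad * b.data, a.shape))
        b.accumulate(_unbroadcast(out.grad * a.data, b.shape))

    out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0), x.requires_grad, (x,))

    def _bw():
        x.accumulate(out.grad * mask)

    out._backward = _bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    # stable logistic
    s = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(x.data))),
                 np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))
    s = s.astype(x.data.dtype)
    out = Tensor(s, x.requires_grad, (x,))

    def _bw():
        x.accumulate(out.grad * s * (1.0 - s))

    out._backward = _bw
    return out


def _pair(v) -> tuple[int, int]:
    return (v, v) if np.isscalar(v) else tuple(v)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding=0, dilation=1) -> Tensor:
    """2-D convolution (cross-correlation), stride 1.

    x: (N, C_in, H, W); w: (C_out, C_in, kh, kw); b: (C_out,) or None.
    ``padding`` / ``dilation`` are ints or (h, w) pairs; zero padding.
    """
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    N, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input has {C}, weight expects {Cw}")
    Ho = H + 2 * ph - (kh - 1) * dh
    Wo = W + 2 * pw - (kw - 1) * dw
    if Ho < 1 or Wo < 1:
        raise ValueError("conv2d: kernel extent exceeds padded input")

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    acc = np.zeros((N, Ho, Wo, O), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i * dh:i * dh + Ho, j * dw:j * dw + Wo]
            # (N,C,Ho,Wo) x (O,C) -> (N,Ho,Wo,O)
            acc += np.tensordot(xs, w.data[:, :, i, j], axes=([1], [1]))
    out_data = acc.transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)
    req = any(p.requires_grad for p in parents)
    out = Tensor(np.ascontiguousarray(out_data), req, parents)

    def _bw():
        go = out.grad  # (N,O,Ho,Wo)
        gacc = np.ascontiguousarray(go.transpose(0, 2, 3, 1))  # (N,Ho,Wo,O)
        if b is not None and b.requires_grad:
            b.accumulate(go.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        need_w = w.requires_grad
        gxp = np.zeros((N, H + 2 * ph, W + 2 * pw, C), dtype=go.dtype) if need_x else None
        gw = np.zeros_like(w.data) if need_w else None
        for i in range(kh):
            for j in range(kw):
                if need_w:
                    xs = xp[:, :, i * dh:i * dh + Ho, j * dw:j * dw + Wo]
                    # (N,Ho,Wo,O) x (N,C,Ho,Wo) -> (O,C)
                    gw[:, :, i, j] = np.tensordot(gacc, xs, axes=([0, 1, 2], [0, 2, 3]))
                if need_x:
                    # (N,Ho,Wo,O) x (O,C) -> (N,Ho,Wo,C)
                    gxp[:, i * dh:i * dh + Ho, j * dw:j * dw + Wo, :] += np.tensordot(
                        gacc, w.data[:, :, i, j], axes=([3], [0]))
        if need_w:
            w.accumulate(gw)
        if need_x:
            gx = gxp.transpose(0, 3, 1, 2)
            if ph or pw:
                gx = gx[:, :, ph:ph + H, pw:pw + W]
            x.accumulate(np.ascontiguousarray(gx))

    out._backward = _bw
    return out


def conv_transpose2d_2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling).

    x: (N, C_in, H, W); w: (C_in, C_out, 2, 2) -> (N, C_out, 2H, 2W).
    """
    N, C, H, W = x.shape
    Ci, O, kh, kw = w.shape
    if Ci != C:
        raise ValueError(f"conv_transpose2d channel mismatch: input {C}, weight {Ci}")
    # (N,C,H,W) x (C,O,2,2) -> (N,H,W,O,2,2)
    y = np.tensordot(x.data, w.data, axes=([1], [0]))
    out_data = np.ascontiguousarray(
        y.transpose(0, 3, 1, 4, 2, 5).reshape(N, O, 2 * H, 2 * W))
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, any(p.requires_grad for p in parents), parents)

    def _bw():
        go = out.grad.reshape(N, O, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)  # (N,H,W,O,2,2)
        if b is not None and b.requires_grad:
            b.accumulate(out.grad.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            # (N,C,H,W) x (N,H,W,O,2,2) -> (C,O,2,2)
            w.accumulate(np.tensordot(x.data, go, axes=([0, 2, 3], [0, 1, 2])))
        if x.requires_grad:
            # (N,H,W,O,2,2) x (C,O,2,2) -> (N,H,W,C)
            gx = np.tensordot(go, w.data, axes=([3, 4, 5], [1, 2, 3]))
            x.accumulate(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))

    out._backward = _bw
    return out


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Ties resolve to the first (row-major) cell."""
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2d requires even spatial dims, got {H}x{W}")
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xf = np.ascontiguousarray(xr).reshape(N, C, H // 2, W // 2, 4)
    idx = xf.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))

    def _bw():
        gf = np.zeros_like(xf)
        np.put_along_axis(gf, idx[..., None], out.grad[..., None], axis=-1)
        gx = gf.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x.accumulate(np.ascontiguousarray(gx).reshape(N, C, H, W))

    out._backward = _bw
    return out


def _linear_resize_axis(n_in: int, n_out: int):
    """Neighbour indices and weights for 1-D bilinear resize (half-pixel centres)."""
    c = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.clip(np.floor(c).astype(np.intp), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    w1 = np.clip(c - np.floor(c), 0.0, 1.0)
    return i0, i1, 1.0 - w1, w1


def _resize_fwd_axis(a: np.ndarray, axis: int, plan) -> np.ndarray:
    i0, i1, w0, w1 = plan
    m = np.moveaxis(a, axis, 0)
    shp = (-1,) + (1,) * (m.ndim - 1)
    r = m[i0] * w0.astype(a.dtype).reshape(shp) + m[i1] * w1.astype(a.dtype).reshape(shp)
    return np.moveaxis(r, 0, axis)


def _resize_bwd_axis(g: np.ndarray, axis: int, n_in: int, plan) -> np.ndarray:
    i0, i1, w0, w1 = plan
    gm = np.moveaxis(g, axis, 0)
    shp = (-1,) + (1,) * (gm.ndim - 1)
    out = np.zeros((n_in,) + gm.shape[1:], dtype=g.dtype)
    np.add.at(out, i0, gm * w0.astype(g.dtype).reshape(shp))
    np.add.at(out, i1, gm * w1.astype(g.dtype).reshape(shp))
    return np.moveaxis(out, 0, axis)


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of (N,C,H,W) to spatial ``size`` (half-pixel convention)."""
    N, C, H, W = x.shape
    Ho, Wo = size
    plan_h = _linear_resize_axis(H, Ho)
    plan_w = _linear_resize_axis(W, Wo)
    y = _resize_fwd_axis(x.data, 2, plan_h)
    y = _resize_fwd_axis(y, 3, plan_w)
    out = Tensor(y, x.requires_grad, (x,))

    def _bw():
        g = _resize_bwd_axis(out.grad, 3, W, plan_w)
        g = _resize_bwd_axis(g, 2, H, plan_h)
        x.accumulate(g)

    out._backward = _bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(a, b)
            t.accumulate(out.grad[tuple(sl)])

    out._backward = _bw
    return out


def mean_axis(x: Tensor, axis: int) -> Tensor:
    """Mean over one axis, keepdims=True (used by strip pooling)."""
    n = x.shape[axis]
    out = Tensor(x.data.mean(axis=axis, keepdims=True), x.requires_grad, (x,))

    def _bw():
        x.accumulate(np.broadcast_to(out.grad / n, x.shape).astype(x.data.dtype))

    out._backward = _bw
    return out


def sum_all(x: Tensor) -> Tensor:
    out = Tensor(np.asarray(x.data.sum(), dtype=x.data.dtype), x.requires_grad, (x,))

    def _bw():
        x.accumulate(np.broadcast_to(out.grad, x.shape).astype(x.data.dtype))

    out._backward = _bw
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation on (N,C,H,W).

    In training mode normalises with batch statistics and updates the running
    buffers in place; in eval mode uses the stored running statistics.
    """
    N, C, H, W = x.shape
    if training:
        m = N * H * W
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        # unbiased running variance, biased batch variance for normalisation
        running_var += momentum * (var * (m / max(m - 1, 1)))
    else:
        mu = running_mean
        var = running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * ivar[None, :, None, None]
    xhat = xhat.astype(x.data.dtype)
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(out_data, x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))

    def _bw():
        go = out.grad
        if beta.requires_grad:
            beta.accumulate(go.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma.accumulate((go * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxh = go * gamma.data[None, :, None, None]
            if training:
                m = N * H * W
                s1 = gxh.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (gxh - s1 / m - xhat * s2 / m) * ivar[None, :, None, None]
            else:
                gx = gxh * ivar[None, :, None, None]
            x.accumulate(gx.astype(x.data.dtype))

    out._backward = _bw
    return out


def cross_entropy_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Multinomial cross-entropy, mean over all pixels.

    Per pixel with score vector x and true class c the loss is
    ``-x[c] + log(sum_j exp(x[j]))``, evaluated with the log-sum-exp shift
    for numerical stability. logits: (N,K,H,W); labels: (N,H,W) ints in
    [0, K).
    """
    labels = np.asarray(labels)
    N, K, H, W = logits.shape
    if labels.shape != (N, H, W):
        raise ValueError(f"labels shape {labels.shape} does not match logits {(N, H, W)}")
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError(f"labels must lie in [0, {K}); got range "
                         f"[{labels.min()}, {labels.max()}]")
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    sez = ez.sum(axis=1, keepdims=True)
    lse = (zmax + np.log(sez))[:, 0]  # (N,H,W)
    picked = np.take_along_axis(z, labels[:, None], axis=1)[:, 0]
    npix = N * H * W
    loss = (lse - picked).sum() / npix
    out = Tensor(np.asarray(loss, dtype=z.dtype), logits.requires_grad, (logits,))

    def _bw():
        p = ez / sez
        ni, hi, wi = np.indices((N, H, W), sparse=True)
        p[ni, labels, hi, wi] -= 1.0  # softmax minus one-hot
        logits.accumulate((out.grad * p / npix).astype(z.dtype))

    out._backward = _bw
    return out
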