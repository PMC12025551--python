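"""Differentiable array operations (NCHW layout)."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, make_op


def _as4(pad):
    """Normalize padding to ((top, bottom), (left, right))."""
    if isinstance(pad, int):
        return ((pad, pad), (pad, pad))
    (a, b), (c, d) = pad
    return ((a, b), (c, d))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, pad=0) -> Tensor:
    """2D convolution (cross-correlation), stride 1.

    ``x``: (N, Cin, H, W); ``w``: (Cout, Cin, kh, kw); ``b``: (Cout,) or None.
    ``pad``: int or ((top, bottom), (left, right)).
    """
    (pt, pb), (pl, pr) = _as4(pad)
    xd = x.data
    wd = w.data
    n, cin, h, wid = xd.shape
    cout, cin_w, kh, kw = wd.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin_w}")
    xp = np.pad(xd, ((0, 0), (0, 0), (pt, pb), (pl, pr))) if (pt or pb or pl or pr) else xd
    ho = xp.shape[2] - kh + 1
    wo = xp.shape[3] - kw + 1
    if ho <= 0 or wo <= 0:
        raise ValueError("input smaller than kernel after padding")

    out = np.zeros((n, ho, wo, cout), dtype=np.float32)
    for di in range(kh):
        for dj in range(kw):
            # (N, ho, wo, Cout) += (N, Cin, ho, wo) x (Cout, Cin)
            out += np.tensordot(
                xp[:, :, di : di + ho, dj : dj + wo], wd[:, :, di, dj], axes=([1], [1])
            )
    if b is not None:
        out += b.data
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (N, ho, wo, Cout)
        gw = np.empty_like(wd)
        gxp = np.zeros_like(xp)
        for di in range(kh):
            for dj in range(kw):
                patch = xp[:, :, di : di + ho, dj : dj + wo]
                gw[:, :, di, dj] = np.tensordot(gt, patch, axes=([0, 1, 2], [0, 2, 3]))
                gxp[:, :, di : di + ho, dj : dj + wo] += np.tensordot(
                    gt, wd[:, :, di, dj], axes=([3], [0])
                ).transpose(0, 3, 1, 2)
        gx = gxp[:, :, pt : xp.shape[2] - pb, pl : xp.shape[3] - pr]
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, gt.sum(axis=(0, 1, 2))))
        return grads

    return make_op(out, parents, backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        return [(x, g * mask)]

    return make_op(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        return [(x, g * y * (1.0 - y))]

    return make_op(y, (x,), backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    h2, w2 = h // 2, w // 2
    blocks = (
        x.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    )
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gb = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gx = gb.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return [(x, gx)]

    return make_op(out, (x,), backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by a factor of 2 in both spatial dims."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.data.shape

    def backward(g):
        gx = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        return [(x, gx)]

    return make_op(out, (x,), backward)


def concat_channels(xs: list[Tensor]) -> Tensor:
    out = np.concatenate([t.data for t in xs], axis=1)
    sizes = [t.data.shape[1] for t in xs]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return [(t, g[:, offsets[i] : offsets[i + 1]]) for i, t in enumerate(xs)]

    return make_op(out, tuple(xs), backward)


def mean_stack(xs: list[Tensor]) -> Tensor:
    """Elementwise mean of same-shape tensors (the fractal join rule)."""
    k = len(xs)
    out = xs[0].data.copy()
    for t in xs[1:]:
        out += t.data
    out /= k

    def backward(g):
        gk = g / k
        return [(t, gk) for t in xs]

    return make_op(out, tuple(xs), backward)


def add(x: Tensor, y: Tensor) -> Tensor:
    out = x.data + y.data

    def backward(g):
        return [(x, g), (y, g)]

    return make_op(out, (x, y), backward)


def mul_gate(x: Tensor, alpha: Tensor) -> Tensor:
    """Multiply features (N,C,H,W) by a one-channel gate (N,1,H,W)."""
    out = x.data * alpha.data

    def backward(g):
        return [(x, g * alpha.data), (alpha, (g * x.data).sum(axis=1, keepdims=True))]

    return make_op(out, (x, alpha), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; apply only during training."""
    if p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    out = x.data * mask

    def backward(g):
        return [(x, g * mask)]

    return make_op(out, (x,), backward)


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Batch normalization over (N, H, W) per channel, training mode.

    Returns (output, batch_mean, batch_var) — the stats are plain arrays
    for the module's running-average update.
    """
    xd = x.data
    mean = xd.mean(axis=(0, 2, 3))
    var = xd.var(axis=(0, 2, 3))
    invstd = 1.0 / np.sqrt(var + eps)
    mr = mean.reshape(1, -1, 1, 1)
    ir = invstd.reshape(1, -1, 1, 1)
    xhat = (xd - mr) * ir
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)
    m = xd.shape[0] * xd.shape[2] * xd.shape[3]

    def backward(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        gr = gamma.data.reshape(1, -1, 1, 1)
        dx = (gr * ir / m) * (
            m * g - dbeta.reshape(1, -1, 1, 1) - xhat * dgamma.reshape(1, -1, 1, 1)
        )
        return [(x, dx.astype(np.float32)), (gamma, dgamma), (beta, dbeta)]

    return make_op(out.astype(np.float32), (x, gamma, beta), backward), mean, var


def batchnorm_eval(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var, eps: float = 1e-5) -> Tensor:
    invstd = 1.0 / np.sqrt(running_var + eps)
    ir = invstd.reshape(1, -1, 1, 1)
    mr = running_mean.reshape(1, -1, 1, 1)
    xhat = (x.data - mr) * ir
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        dx = g * gamma.data.reshape(1, -1, 1, 1) * ir
        return [(x, dx.astype(np.float32)), (gamma, dgamma), (beta, dbeta)]

    return make_op(out.astype(np.float32), (x, gamma, beta), backward)
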