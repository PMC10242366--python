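"""Differentiable operations for 2D segmentation networks.

All image tensors use the NHWC layout (batch, rows, cols, channels).
Convolution weights are ``(kh, kw, c_in, c_out)``; transposed-convolution
weights are ``(2, 2, c_in, c_out)`` with fixed stride 2.

``conv2d`` is evaluated as a sum of kernel-offset shifted matrix products
rather than one big im2col buffer, which bounds peak memory to a single
shifted copy of the input — important for wide dense blocks on full-size
slices.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 correlation. Kernel sides must be odd."""
    x, w = as_tensor(x), as_tensor(w)
    kh, kw, c_in, c_out = w.data.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel sides")
    n, h, wd, cx = x.data.shape
    if cx != c_in:
        raise ValueError(f"channel mismatch: input {cx}, weight {c_in}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    y = np.zeros((n, h, wd, c_out), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            y += xp[:, i : i + h, j : j + wd, :] @ w.data[i, j]
    if b is not None:
        y += b.data

    def backward(g):
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    patch = xp[:, i : i + h, j : j + wd, :]
                    dw[i, j] = np.tensordot(patch, g, axes=([0, 1, 2], [0, 1, 2]))
            w.accumulate_grad(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + h, j : j + wd, :] += g @ w.data[i, j].T
            x.accumulate_grad(dxp[:, ph : ph + h, pw : pw + wd, :])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(y, parents=parents, backward=backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2x2 and stride 2 (doubles H and W)."""
    x, w = as_tensor(x), as_tensor(w)
    if w.data.shape[:2] != (2, 2):
        raise ValueError("conv_transpose2d is fixed to 2x2 kernels")
    n, h, wd, c_in = x.data.shape
    c_out = w.data.shape[3]
    y = np.einsum("nhwc,ijcd->nhiwjd", x.data, w.data, optimize=True)
    y = y.reshape(n, 2 * h, 2 * wd, c_out)
    if b is not None:
        y = y + b.data

    def backward(g):
        gr = g.reshape(n, h, 2, wd, 2, c_out)
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            w.accumulate_grad(
                np.einsum("nhwc,nhiwjd->ijcd", x.data, gr, optimize=True)
            )
        if x.requires_grad:
            x.accumulate_grad(
                np.einsum("nhiwjd,ijcd->nhwc", gr, w.data, optimize=True)
            )

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(y, parents=parents, backward=backward)


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; halves rows and columns."""
    x = as_tensor(x)
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2x2 requires even spatial extents")
    win = x.data.reshape(n, h // 2, 2, w // 2, 2, c)
    win = win.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            dwin = np.zeros((n, h // 2, w // 2, c, 4), dtype=g.dtype)
            np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
            dx = dwin.reshape(n, h // 2, w // 2, c, 2, 2)
            dx = dx.transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)
            x.accumulate_grad(dx)

    return Tensor(y, parents=(x,), backward=backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by a factor of 2 in rows and columns."""
    x = as_tensor(x)
    y = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def backward(g):
        if x.requires_grad:
            n, h2, w2, c = g.shape
            dx = g.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))
            x.accumulate_grad(dx)

    return Tensor(y, parents=(x,), backward=backward)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    y = np.where(mask, x.data, 0)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(np.where(mask, g, 0))

    return Tensor(y, parents=(x,), backward=backward)


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """Parametric ReLU with one trainable slope per channel (last axis)."""
    x, alpha = as_tensor(x), as_tensor(alpha)
    pos = x.data > 0
    y = np.where(pos, x.data, alpha.data * x.data)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(np.where(pos, g, alpha.data * g))
        if alpha.requires_grad:
            da = np.where(pos, 0, g * x.data)
            alpha.accumulate_grad(da.sum(axis=tuple(range(da.ndim - 1))))

    return Tensor(y, parents=(x, alpha), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    with np.errstate(over="ignore"):
        y = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g * y * (1.0 - y))

    return Tensor(y, parents=(x,), backward=backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x.accumulate_grad(y * (g - dot))

    return Tensor(y, parents=(x,), backward=backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.9,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over the (N, H, W) axes.

    ``running_mean``/``running_var`` are updated in place when training.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0, 1, 2)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= momentum
        running_mean += (1 - momentum) * mean
        running_var *= momentum
        running_var += (1 - momentum) * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv
    y = gamma.data * xhat + beta.data

    def backward(g):
        if beta.requires_grad:
            beta.accumulate_grad(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma.accumulate_grad((g * xhat).sum(axis=axes))
        if x.requires_grad:
            if training:
                gx = g * gamma.data
                dx = (
                    gx
                    - gx.mean(axis=axes)
                    - xhat * (gx * xhat).mean(axis=axes)
                ) * inv
                x.accumulate_grad(dx)
            else:
                x.accumulate_grad(g * gamma.data * inv)

    return Tensor(y, parents=(x, gamma, beta), backward=backward)


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean categorical cross-entropy fused with softmax.

    ``onehot`` is a plain array shaped like ``logits`` with exactly one 1 per
    pixel. Returns the scalar loss tensor and the softmax probabilities.
    """
    logits = as_tensor(logits)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=-1, keepdims=True)
    n_pix = int(np.prod(logits.data.shape[:-1]))
    logp = z - np.log(e.sum(axis=-1, keepdims=True))
    loss_val = -(onehot * logp).sum() / n_pix

    def backward(g):
        if logits.requires_grad:
            logits.accumulate_grad(g * (probs - onehot) / n_pix)

    loss = Tensor(
        np.asarray(loss_val, dtype=logits.data.dtype),
        parents=(logits,),
        backward=backward,
    )
    return loss, probs
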