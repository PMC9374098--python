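"""Differentiable 3D network ops (channels-last layout ``(N, X, Y, Z, C)``).

The 3D convolution is computed as a sum over the 27 (or k^3) kernel offsets,
each a single matrix product over the channel axis; this keeps memory at one
padded copy of the input and is the workhorse of the whole network.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "add",
    "channel_slice",
    "add_bias",
    "relu",
    "concat",
    "conv3d",
    "maxpool3d",
    "upsample_nearest",
    "batchnorm",
    "mse_loss",
]


def add_bias(x: Tensor, bias: Tensor) -> Tensor:
    """Add a per-channel bias (shape ``(C,)``) to ``(..., C)`` activations."""
    out = Tensor(x.data + bias.data, parents=(x, bias))

    def _backward(grad):
        x.accumulate(grad)
        bias.accumulate(grad.reshape(-1, grad.shape[-1]).sum(axis=0))

    out.backward_fn = _backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise sum of two same-shape tensors."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    out = Tensor(a.data + b.data, parents=(a, b))

    def _backward(grad):
        a.accumulate(grad)
        b.accumulate(grad)

    out.backward_fn = _backward
    return out


def channel_slice(x: Tensor, start: int, stop: int) -> Tensor:
    """Select channels ``[start:stop)`` of ``(..., C)`` activations."""
    out = Tensor(x.data[..., start:stop], parents=(x,))

    def _backward(grad):
        g = np.zeros_like(x.data)
        g[..., start:stop] = grad
        x.accumulate(g)

    out.backward_fn = _backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, np.float32(0.0)), parents=(x,))

    def _backward(grad):
        x.accumulate(np.where(mask, grad, np.float32(0.0)))

    out.backward_fn = _backward
    return out


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel (last) axis."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=-1), parents=tuple(tensors))
    splits = np.cumsum([t.data.shape[-1] for t in tensors])[:-1]

    def _backward(grad):
        for t, g in zip(tensors, np.split(grad, splits, axis=-1)):
            t.accumulate(g)

    out.backward_fn = _backward
    return out


def _pad_spatial(data: np.ndarray, pads: tuple[int, int, int]) -> np.ndarray:
    return np.pad(
        data,
        ((0, 0), (pads[0], pads[0]), (pads[1], pads[1]), (pads[2], pads[2]), (0, 0)),
        mode="constant",
    )


def conv3d(x: Tensor, weight: Tensor, stride: tuple[int, int, int] = (1, 1, 1)) -> Tensor:
    """'Same'-padded 3D convolution with optional per-axis stride.

    ``x`` is ``(N, X, Y, Z, Cin)``; ``weight`` is ``(kx, ky, kz, Cin, Cout)``
    with odd kernel sizes. With stride ``s`` the output spatial size is
    ``ceil(size / s)`` (samples at indices 0, s, 2s, ... of the same-padded
    result).
    """
    kx, ky, kz, cin, cout = weight.data.shape
    if x.data.shape[-1] != cin:
        raise ValueError(f"input has {x.data.shape[-1]} channels, weight expects {cin}")
    if any(k % 2 == 0 for k in (kx, ky, kz)):
        raise ValueError("kernel sizes must be odd for 'same' padding")
    pads = (kx // 2, ky // 2, kz // 2)
    sx, sy, sz = stride
    n, nx, ny, nz, _ = x.data.shape
    xp = _pad_spatial(x.data, pads)
    ox = -(-nx // sx)
    oy = -(-ny // sy)
    oz = -(-nz // sz)
    out_data = np.zeros((n, ox, oy, oz, cout), dtype=np.float32)
    out_flat = out_data.reshape(-1, cout)
    w = weight.data
    for dx in range(kx):
        for dy in range(ky):
            for dz in range(kz):
                sl = xp[
                    :,
                    dx : dx + nx : sx,
                    dy : dy + ny : sy,
                    dz : dz + nz : sz,
                    :,
                ]
                out_flat += sl.reshape(-1, cin) @ w[dx, dy, dz]
    out = Tensor(out_data, parents=(x, weight))

    def _backward(grad):
        grad = grad.reshape(n, ox, oy, oz, cout)
        g2 = grad.reshape(-1, cout)
        need_dx = x.requires_grad
        dxp = np.zeros_like(xp) if need_dx else None
        dw = np.zeros_like(w)
        for dx_ in range(kx):
            for dy_ in range(ky):
                for dz_ in range(kz):
                    sl = xp[
                        :,
                        dx_ : dx_ + nx : sx,
                        dy_ : dy_ + ny : sy,
                        dz_ : dz_ + nz : sz,
                        :,
                    ]
                    dw[dx_, dy_, dz_] = sl.reshape(-1, cin).T @ g2
                    if need_dx:
                        contrib = (g2 @ w[dx_, dy_, dz_].T).reshape(sl.shape)
                        dxp[
                            :,
                            dx_ : dx_ + nx : sx,
                            dy_ : dy_ + ny : sy,
                            dz_ : dz_ + nz : sz,
                            :,
                        ] += contrib
        weight.accumulate(dw)
        if need_dx:
            px, py, pz = pads
            x.accumulate(dxp[:, px : px + nx, py : py + ny, pz : pz + nz, :])

    out.backward_fn = _backward
    return out


def maxpool3d(x: Tensor, pool: tuple[int, int, int]) -> Tensor:
    """Max pooling with per-axis window = stride; spatial sizes must divide."""
    px, py, pz = pool
    n, nx, ny, nz, c = x.data.shape
    if nx % px or ny % py or nz % pz:
        raise ValueError(f"shape {(nx, ny, nz)} not divisible by pool {pool}")
    blocks = x.data.reshape(n, nx // px, px, ny // py, py, nz // pz, pz, c)
    blocks = blocks.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(
        n, nx // px, ny // py, nz // pz, c, px * py * pz
    )
    arg = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, parents=(x,))

    def _backward(grad):
        dblocks = np.zeros_like(blocks)
        np.put_along_axis(dblocks, arg[..., None], grad[..., None], axis=-1)
        dx = dblocks.reshape(n, nx // px, ny // py, nz // pz, c, px, py, pz)
        dx = dx.transpose(0, 1, 5, 2, 6, 3, 7, 4).reshape(n, nx, ny, nz, c)
        x.accumulate(dx)

    out.backward_fn = _backward
    return out


def upsample_nearest(x: Tensor, factors: tuple[int, int, int]) -> Tensor:
    """Nearest-neighbour upsampling by integer per-axis factors."""
    fx, fy, fz = factors
    data = x.data
    if fx > 1:
        data = np.repeat(data, fx, axis=1)
    if fy > 1:
        data = np.repeat(data, fy, axis=2)
    if fz > 1:
        data = np.repeat(data, fz, axis=3)
    out = Tensor(data, parents=(x,))
    n, nx, ny, nz, c = x.data.shape

    def _backward(grad):
        g = grad.reshape(n, nx, fx, ny, fy, nz, fz, c)
        x.accumulate(g.sum(axis=(2, 4, 6)))

    out.backward_fn = _backward
    return out


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over the batch and spatial axes.

    In training mode batch statistics are used and the running statistics are
    updated in place; in eval mode the running statistics are used.
    """
    axes = (0, 1, 2, 3)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean = running_mean.astype(np.float32)
        var = running_var.astype(np.float32)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))
    m = x.data.size // x.data.shape[-1]

    def _backward(grad):
        gamma.accumulate((grad * xhat).sum(axis=axes))
        beta.accumulate(grad.sum(axis=axes))
        if not x.requires_grad:
            return
        gx = grad * gamma.data
        if training:
            # full batch-stat jacobian
            dxhat_sum = gx.sum(axis=axes)
            dxhat_dot = (gx * xhat).sum(axis=axes)
            dx = (gx - dxhat_sum / m - xhat * dxhat_dot / m) * inv_std
        else:
            dx = gx * inv_std
        x.accumulate(dx.astype(np.float32))

    out.backward_fn = _backward
    return out


def mse_loss(pred: Tensor, target: Tensor) -> Tensor:
    """Mean squared error over all elements."""
    diff = pred.data - target.data
    out = Tensor(np.float32(np.mean(diff.astype(np.float64) ** 2)), parents=(pred, target))
    scale = np.float32(2.0 / diff.size)

    def _backward(grad):
        g = grad * scale * diff
        pred.accumulate(g)
        if target.requires_grad:
            target.accumulate(-g)

    out.backward_fn = _backward
    return out
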