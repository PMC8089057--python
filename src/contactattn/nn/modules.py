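"""Neural-network layers built on the autograd engine.

All layers use a channel-last layout and no batch dimension (the training
protocol processes one protein at a time): 1D features are ``(L, C)`` arrays
and 2D feature maps are ``(L, L, C)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, cat

__all__ = [
    "Module", "Linear", "Conv1d", "Conv2d", "InstanceNorm", "BiLSTM",
    "SqueezeExcite", "maxout", "truncated_normal", "window_gather",
    "window_inbounds_mask",
]


def truncated_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    """Normal(0, std) resampled until within +/- 2 std (weight initializer)."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2.0 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2.0 * std
    return x


class Module:
    """Base class: tracks parameters through attribute registration."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{key}.{i}", item))
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 init_std: float | None = None):
        std = init_std if init_std is not None else float(np.sqrt(2.0 / d_in))
        self.w = Tensor(truncated_normal(rng, (d_in, d_out), std), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """'same'-padded 1D convolution on (L, C_in) -> (L, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 init_std: float | None = None):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        std = init_std if init_std is not None else float(np.sqrt(2.0 / (kernel * c_in)))
        self.w = Tensor(truncated_normal(rng, (kernel * c_in, c_out), std),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        k, p = self.kernel, self.kernel // 2
        L, c_in = x.shape
        xp = np.pad(x.data, ((p, p), (0, 0)))
        # (L, k, c_in) -> (L, k*c_in)
        cols = sliding_window_view(xp, k, axis=0).transpose(0, 2, 1).reshape(L, k * c_in)
        w, b = self.w, self.b
        out_data = cols @ w.data + b.data

        def backward(g):
            if w.requires_grad:
                w._accum(cols.T @ g)
            if b.requires_grad:
                b._accum(g.sum(axis=0))
            if x.requires_grad:
                dcols = (g @ w.data.T).reshape(L, k, c_in)
                gxp = np.zeros_like(xp)
                for d in range(k):
                    gxp[d:d + L] += dcols[:, d, :]
                x._accum(gxp[p:p + L])

        return Tensor.from_op(out_data, (x, w, b), backward)


class Conv2d(Module):
    """'same'-padded 2D convolution on (L, L, C_in) -> (L, L, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 init_std: float | None = None):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        std = init_std if init_std is not None else float(
            np.sqrt(2.0 / (kernel * kernel * c_in)))
        self.w = Tensor(truncated_normal(rng, (kernel * kernel * c_in, c_out), std),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        k, p = self.kernel, self.kernel // 2
        H, W, c_in = x.shape
        if k == 1:
            # fast path: a 1x1 convolution is a pointwise linear map
            return x @ self.w + self.b
        xp = np.pad(x.data, ((p, p), (p, p), (0, 0)))
        # (H, W, c_in, k, k) -> (H*W, k*k*c_in)
        win = sliding_window_view(xp, (k, k), axis=(0, 1))
        cols = win.transpose(0, 1, 3, 4, 2).reshape(H * W, k * k * c_in)
        w, b = self.w, self.b
        out_data = (cols @ w.data + b.data).reshape(H, W, self.c_out)

        def backward(g):
            gf = g.reshape(H * W, self.c_out)
            if w.requires_grad:
                w._accum(cols.T @ gf)
            if b.requires_grad:
                b._accum(gf.sum(axis=0))
            if x.requires_grad:
                dcols = (gf @ w.data.T).reshape(H, W, k, k, c_in)
                gxp = np.zeros_like(xp)
                for di in range(k):
                    for dj in range(k):
                        gxp[di:di + H, dj:dj + W] += dcols[:, :, di, dj, :]
                x._accum(gxp[p:p + H, p:p + W])

        return Tensor.from_op(out_data, (x, w, b), backward)


class InstanceNorm(Module):
    """Normalize each channel over its spatial extent, then scale and shift.

    Works for both (L, C) and (L, L, C) inputs: statistics are taken over all
    leading (spatial) axes independently per channel.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        mu = x.mean(axis=axes, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=axes, keepdims=True)
        xn = centered * (var + self.eps).pow(-0.5)
        return xn * self.gamma + self.beta


class LSTMCellParams(Module):
    """Fused-gate LSTM parameters (input, forget, cell, output)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        std = float(np.sqrt(1.0 / max(d_in, 1)))
        self.wx = Tensor(truncated_normal(rng, (d_in, 4 * hidden), std),
                         requires_grad=True)
        self.wh = Tensor(truncated_normal(rng, (hidden, 4 * hidden),
                                          float(np.sqrt(1.0 / hidden))),
                         requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)
        self.hidden = hidden


class BiLSTM(Module):
    """Bidirectional LSTM over (L, d_in); outputs (L, 2*hidden).

    Forward and reverse passes are run independently and their per-position
    outputs concatenated, so position i sees context from both chain ends.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTMCellParams(d_in, hidden, rng)
        self.bwd = LSTMCellParams(d_in, hidden, rng)
        self.hidden = hidden

    def _run(self, x: Tensor, cell: LSTMCellParams, reverse: bool) -> Tensor:
        L = x.shape[0]
        H = cell.hidden
        h = Tensor(np.zeros((1, H)))
        c = Tensor(np.zeros((1, H)))
        order = range(L - 1, -1, -1) if reverse else range(L)
        outputs: list[Tensor | None] = [None] * L
        for t in order:
            xt = x[t:t + 1, :]
            gates = xt @ cell.wx + h @ cell.wh + cell.b
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[t] = h
        return cat(outputs, axis=0)

    def __call__(self, x: Tensor) -> Tensor:
        return cat([self._run(x, self.fwd, False), self._run(x, self.bwd, True)],
                   axis=-1)


class SqueezeExcite(Module):
    """Squeeze-and-excitation channel gate.

    Global average pool per channel, a two-layer bottleneck dense network with
    a sigmoid gate, then per-channel rescaling of the input map.
    """

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator):
        mid = max(1, channels // ratio)
        self.fc1 = Linear(channels, mid, rng)
        self.fc2 = Linear(mid, channels, rng)

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        z = x.mean(axis=axes, keepdims=False).reshape(1, x.shape[-1])
        gate = self.fc2(self.fc1(z).relu()).sigmoid()
        return x * gate

    def gate_values(self, x: Tensor) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        z = x.mean(axis=axes, keepdims=False).reshape(1, x.shape[-1])
        return self.fc2(self.fc1(z).relu()).sigmoid().data.ravel()


def maxout(x: Tensor) -> Tensor:
    """Pairwise max over the last axis: channels (2k, 2k+1) -> one channel."""
    if x.shape[-1] % 2 != 0:
        raise ValueError(f"maxout needs an even channel count, got {x.shape[-1]}")
    return x[..., 0::2].maximum(x[..., 1::2])


def window_inbounds_mask(L: int, n: int) -> np.ndarray:
    """Boolean (L, L, n*n): which row-major window cells fall inside the map."""
    p = n // 2
    ones = np.pad(np.ones((L, L)), ((p, p), (p, p)))
    win = sliding_window_view(ones, (n, n), axis=(0, 1))
    return win.reshape(L, L, n * n) > 0.5


def window_gather(x: Tensor, n: int) -> Tensor:
    """Gather the n x n neighbourhood of every map cell (zero padded).

    Input (L, L, c); output (L, L, n*n, c) where the third axis enumerates the
    window offsets in row-major order. This is the stretching operation that
    rewrites each position as its flattened surrounding region so attention can
    be taken over the window axis.
    """
    if n % 2 == 0:
        raise ValueError("window size n must be odd")
    L, L2, c = x.shape
    p = n // 2
    xp = np.pad(x.data, ((p, p), (p, p), (0, 0)))
    # (L, L, c, n, n) -> (L, L, n, n, c) -> (L, L, n*n, c)
    win = sliding_window_view(xp, (n, n), axis=(0, 1))
    out_data = win.transpose(0, 1, 3, 4, 2).reshape(L, L, n * n, c)

    def backward(g):
        if not x.requires_grad:
            return
        gw = g.reshape(L, L, n, n, c)
        gxp = np.zeros_like(xp)
        for di in range(n):
            for dj in range(n):
                gxp[di:di + L, dj:dj + L] += gw[:, :, di, dj, :]
        x._accum(gxp[p:p + L, p:p + L])

    return Tensor.from_op(out_data, (x,), backward)
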