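"""Attention operators for contact prediction.

Two attention mechanisms are implemented:

* **Sequence attention** — multi-head scaled dot-product attention over the
  residue axis. Per head h, with per-head input slice ``X_h`` of width
  ``d_att``::

      Q = X_h W_Q,  K = X_h W_K,  V = X_h W_V
      W_att = softmax(Q K^T / sqrt(d_att))     (row-wise)
      Z_h   = W_att V

  Head outputs are concatenated. The row-stochastic ``W_att`` matrices are
  returned for interpretation: entry (i, j) is the importance of residue j to
  residue i, and each row sums to 1.

* **Regional attention** — windowed attention on an (L, L, c) feature map.
  Each map cell is first rewritten as its flattened n x n surrounding region
  in row-major order (the region-stretching operation, zero padded at the map
  border); the cell's channel vector forms the query, the window cells form
  keys and values, and a masked softmax over the window distributes exactly
  one unit of weight over in-bounds cells, so each output position is a
  weighted sum of its surrounding region.

Each operator has a functional numpy surface (used by the oracle-equivalence
tests and the interpretation pipeline) and a Tensor core shared with the
trainable network layers, so the tested math and the trained math are the
same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.tensor import Tensor, cat, softmax
from .nn.modules import (
    Module, truncated_normal, window_gather, window_inbounds_mask,
)

__all__ = [
    "Attention1DParams", "Attention1DWeights", "RegionalAttentionParams",
    "RegionalAttentionWeights", "AttentionRecord",
    "multihead_attention_1d", "tile_1d_to_2d", "region_stretch",
    "regional_attention", "init_attention1d_params",
    "init_regional_attention_params", "Attention1DLayer",
    "RegionalAttentionLayer", "tile_tensor",
]


# ---------------------------------------------------------------------------
# Parameter and weight containers

@dataclass
class Attention1DParams:
    """Sequence-attention parameters (numpy arrays).

    ``w_in``/``b_in`` project the encoder output to ``n_heads * d_att``
    channels; ``w_q``, ``w_k``, ``w_v`` hold one (d_att, d_att) matrix per
    head.
    """

    w_in: np.ndarray   # (d_in, n_heads * d_att)
    b_in: np.ndarray   # (n_heads * d_att,)
    w_q: np.ndarray    # (n_heads, d_att, d_att)
    w_k: np.ndarray
    w_v: np.ndarray

    def __post_init__(self):
        for name in ("w_in", "b_in", "w_q", "w_k", "w_v"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite entries in {name}")
            setattr(self, name, arr)
        if self.w_q.shape != self.w_k.shape or self.w_q.shape != self.w_v.shape:
            raise ValueError("per-head matrices must share shape")

    @property
    def n_heads(self) -> int:
        return self.w_q.shape[0]

    @property
    def d_att(self) -> int:
        return self.w_q.shape[1]


@dataclass
class Attention1DWeights:
    """Captured sequence-attention scores: (n_heads, L, L), row-stochastic."""

    w_att: np.ndarray

    def __post_init__(self):
        self.w_att = np.asarray(self.w_att, dtype=np.float64)
        if self.w_att.ndim != 3 or self.w_att.shape[1] != self.w_att.shape[2]:
            raise ValueError(f"expected (heads, L, L), got {self.w_att.shape}")
        if (self.w_att < -1e-12).any():
            raise ValueError("attention weights must be non-negative")
        rows = self.w_att.sum(axis=-1)
        if not np.allclose(rows, 1.0, atol=1e-5):
            raise ValueError("every attention row must sum to 1")

    @property
    def n_heads(self) -> int:
        return self.w_att.shape[0]

    @property
    def length(self) -> int:
        return self.w_att.shape[1]


@dataclass
class RegionalAttentionParams:
    """Regional-attention parameters (numpy arrays), window size ``n`` odd."""

    n: int
    w_q: np.ndarray    # (n_heads, c, d)
    w_k: np.ndarray
    w_v: np.ndarray
    w_out: np.ndarray  # (n_heads * d, c_out)
    b_out: np.ndarray  # (c_out,)

    def __post_init__(self):
        if self.n % 2 == 0 or self.n < 1:
            raise ValueError("window size n must be odd and >= 1")
        for name in ("w_q", "w_k", "w_v", "w_out", "b_out"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))

    @property
    def n_heads(self) -> int:
        return self.w_q.shape[0]

    @property
    def channels(self) -> int:
        return self.w_q.shape[1]

    @property
    def d(self) -> int:
        return self.w_q.shape[2]


@dataclass
class RegionalAttentionWeights:
    """Captured window distributions: (L, L, n_heads, n*n) plus bounds mask.

    For every (center, head) the weights over in-bounds window cells sum to 1
    and out-of-bounds cells carry exactly zero weight.
    """

    weights: np.ndarray       # (L, L, n_heads, n*n)
    inbounds: np.ndarray      # (L, L, n*n) boolean

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.inbounds = np.asarray(self.inbounds, dtype=bool)
        L = self.weights.shape[0]
        n2 = self.weights.shape[3]
        if self.inbounds.shape != (L, L, n2):
            raise ValueError("in-bounds mask shape mismatch")
        if (self.weights[~np.broadcast_to(self.inbounds[:, :, None, :],
                                          self.weights.shape)] != 0).any():
            raise ValueError("out-of-bounds cells must have exactly zero weight")
        sums = self.weights.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("in-bounds window weights must sum to 1")

    @property
    def n(self) -> int:
        return int(round(np.sqrt(self.weights.shape[3])))

    @property
    def n_heads(self) -> int:
        return self.weights.shape[2]

    @property
    def length(self) -> int:
        return self.weights.shape[0]


@dataclass
class AttentionRecord:
    """Attention captured from one forward pass, with provenance."""

    sequence: Attention1DWeights | None = None
    regional: RegionalAttentionWeights | None = None
    protein_id: str = ""
    variant: str = ""
    checkpoint: str = ""


# ---------------------------------------------------------------------------
# Initialization

def init_attention1d_params(d_in: int, n_heads: int, d_att: int,
                            rng: np.random.Generator) -> Attention1DParams:
    std_in = float(np.sqrt(2.0 / d_in))
    std_h = float(np.sqrt(1.0 / d_att))
    return Attention1DParams(
        w_in=truncated_normal(rng, (d_in, n_heads * d_att), std_in),
        b_in=np.zeros(n_heads * d_att),
        w_q=truncated_normal(rng, (n_heads, d_att, d_att), std_h),
        w_k=truncated_normal(rng, (n_heads, d_att, d_att), std_h),
        w_v=truncated_normal(rng, (n_heads, d_att, d_att), std_h),
    )


def init_regional_attention_params(channels: int, n_heads: int, d: int,
                                   c_out: int, n: int,
                                   rng: np.random.Generator
                                   ) -> RegionalAttentionParams:
    std = float(np.sqrt(1.0 / channels))
    return RegionalAttentionParams(
        n=n,
        w_q=truncated_normal(rng, (n_heads, channels, d), std),
        w_k=truncated_normal(rng, (n_heads, channels, d), std),
        w_v=truncated_normal(rng, (n_heads, channels, d), std),
        w_out=truncated_normal(rng, (n_heads * d, c_out),
                               float(np.sqrt(1.0 / (n_heads * d)))),
        b_out=np.zeros(c_out),
    )


# ---------------------------------------------------------------------------
# Tensor cores (shared by the functional API and the network layers)

def _attention_1d_core(x: Tensor, w_in: Tensor, b_in: Tensor, w_q: Tensor,
                       w_k: Tensor, w_v: Tensor, n_heads: int, d_att: int
                       ) -> tuple[Tensor, np.ndarray]:
    proj = x @ w_in + b_in                      # (L, H*d)
    scale = 1.0 / np.sqrt(d_att)
    outs, weights = [], []
    for h in range(n_heads):
        xh = proj[:, h * d_att:(h + 1) * d_att]  # (L, d)
        q = xh @ w_q[h]
        k = xh @ w_k[h]
        v = xh @ w_v[h]
        att = softmax((q @ k.T) * scale, axis=-1)  # (L, L), row-stochastic
        outs.append(att @ v)
        weights.append(att.data)
    return cat(outs, axis=-1), np.stack(weights, axis=0)


def _regional_attention_core(f: Tensor, params_t: dict, n: int, n_heads: int,
                             d: int) -> tuple[Tensor, np.ndarray, np.ndarray]:
    L = f.shape[0]
    n2 = n * n
    stretched = window_gather(f, n)              # (L, L, n2, c)
    inb = window_inbounds_mask(L, n)             # (L, L, n2)
    bias = Tensor((inb.astype(np.float64) - 1.0) * 1e9)
    mask_t = Tensor(inb.astype(np.float64))
    scale = 1.0 / np.sqrt(d)
    outs, weights = [], []
    for h in range(n_heads):
        q = f @ params_t["w_q"][h]               # (L, L, d)
        k = stretched @ params_t["w_k"][h]       # (L, L, n2, d)
        v = stretched @ params_t["w_v"][h]
        logits = (k @ q.reshape(L, L, d, 1)).reshape(L, L, n2) * scale + bias
        w = softmax(logits, axis=-1) * mask_t    # exact zeros out of bounds
        outs.append((w.reshape(L, L, 1, n2) @ v).reshape(L, L, d))
        weights.append(w.data)
    out = cat(outs, axis=-1) @ params_t["w_out"] + params_t["b_out"]
    return out, np.stack(weights, axis=2), inb


def tile_tensor(z: Tensor) -> Tensor:
    """Tile (L, d) to (L, L, 2d): row block repeats rows, column block columns."""
    L, d = z.shape
    data = z.data
    out_data = np.concatenate(
        [np.broadcast_to(data[:, None, :], (L, L, d)),
         np.broadcast_to(data[None, :, :], (L, L, d))], axis=-1)

    def backward(g):
        if z.requires_grad:
            z._accum(g[:, :, :d].sum(axis=1) + g[:, :, d:].sum(axis=0))

    return Tensor.from_op(out_data, (z,), backward)


# ---------------------------------------------------------------------------
# Functional operators

def multihead_attention_1d(x: np.ndarray, params: Attention1DParams
                           ) -> tuple[np.ndarray, Attention1DWeights]:
    """Multi-head scaled dot-product attention over residues.

    Returns the concatenated head outputs ``Z`` of shape
    ``(L, n_heads * d_att)`` and the row-stochastic attention weights.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("non-finite attention input")
    z, w = _attention_1d_core(
        Tensor(x), Tensor(params.w_in), Tensor(params.b_in), Tensor(params.w_q),
        Tensor(params.w_k), Tensor(params.w_v), params.n_heads, params.d_att)
    return z.data, Attention1DWeights(w_att=w)


def tile_1d_to_2d(z: np.ndarray) -> np.ndarray:
    """Tile (L, d) to (L, L, 2d): out[i, j] = concat(Z[i], Z[j])."""
    z = np.asarray(z, dtype=np.float64)
    L, d = z.shape
    return np.concatenate([np.broadcast_to(z[:, None, :], (L, L, d)),
                           np.broadcast_to(z[None, :, :], (L, L, d))],
                          axis=-1).copy()


def region_stretch(f: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Rewrite each map cell as its flattened n x n window (zero padded).

    ``f`` is (L, L, c); the output is (L, L, c, n*n) where index w of the last
    axis enumerates window offsets in row-major order, together with the
    (L, L, n*n) in-bounds mask.
    """
    if n % 2 == 0:
        raise ValueError("window size n must be odd")
    f = np.asarray(f, dtype=np.float64)
    L = f.shape[0]
    gathered = window_gather(Tensor(f), n).data        # (L, L, n2, c)
    return gathered.transpose(0, 1, 3, 2).copy(), window_inbounds_mask(L, n)


def regional_attention(f: np.ndarray, params: RegionalAttentionParams
                       ) -> tuple[np.ndarray, RegionalAttentionWeights]:
    """Windowed attention over each cell's n x n region.

    Returns the projected output map (L, L, c_out) and the captured window
    distributions.
    """
    f = np.asarray(f, dtype=np.float64)
    if not np.isfinite(f).all():
        raise ValueError("non-finite attention input")
    if f.shape[2] != params.channels:
        raise ValueError(f"feature channels {f.shape[2]} != "
                         f"params channels {params.channels}")
    params_t = {k: Tensor(getattr(params, k))
                for k in ("w_q", "w_k", "w_v", "w_out", "b_out")}
    out, w, inb = _regional_attention_core(Tensor(f), params_t, params.n,
                                           params.n_heads, params.d)
    return out.data, RegionalAttentionWeights(weights=w, inbounds=inb)


# ---------------------------------------------------------------------------
# Trainable layers

class Attention1DLayer(Module):
    def __init__(self, d_in: int, n_heads: int, d_att: int,
                 rng: np.random.Generator):
        self.n_heads, self.d_att = n_heads, d_att
        p = init_attention1d_params(d_in, n_heads, d_att, rng)
        self.w_in = Tensor(p.w_in, requires_grad=True)
        self.b_in = Tensor(p.b_in, requires_grad=True)
        self.w_q = Tensor(p.w_q, requires_grad=True)
        self.w_k = Tensor(p.w_k, requires_grad=True)
        self.w_v = Tensor(p.w_v, requires_grad=True)

    def __call__(self, x: Tensor) -> tuple[Tensor, np.ndarray]:
        return _attention_1d_core(x, self.w_in, self.b_in, self.w_q, self.w_k,
                                  self.w_v, self.n_heads, self.d_att)


class RegionalAttentionLayer(Module):
    def __init__(self, channels: int, n_heads: int, d: int, c_out: int, n: int,
                 rng: np.random.Generator):
        self.n, self.n_heads, self.d = n, n_heads, d
        p = init_regional_attention_params(channels, n_heads, d, c_out, n, rng)
        self.w_q = Tensor(p.w_q, requires_grad=True)
        self.w_k = Tensor(p.w_k, requires_grad=True)
        self.w_v = Tensor(p.w_v, requires_grad=True)
        self.w_out = Tensor(p.w_out, requires_grad=True)
        self.b_out = Tensor(p.b_out, requires_grad=True)

    def __call__(self, f: Tensor) -> tuple[Tensor, np.ndarray, np.ndarray]:
        params_t = {"w_q": self.w_q, "w_k": self.w_k, "w_v": self.w_v,
                    "w_out": self.w_out, "b_out": self.b_out}
        return _regional_attention_core(f, params_t, self.n, self.n_heads, self.d)
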