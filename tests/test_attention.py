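"""Oracle equivalence and invariants of the attention operators.

Each operator is compared against a naive per-position loop implementation
written independently of the vectorized path."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contactattn.attention import (
    Attention1DParams, init_attention1d_params, init_regional_attention_params,
    multihead_attention_1d, region_stretch, regional_attention, tile_1d_to_2d,
)


# ---------------------------------------------------------------------------
# Naive oracles

def naive_attention_1d(x, p: Attention1DParams):
    L = x.shape[0]
    proj = x @ p.w_in + p.b_in
    z_heads, w_heads = [], []
    for h in range(p.n_heads):
        xh = proj[:, h * p.d_att:(h + 1) * p.d_att]
        q, k, v = xh @ p.w_q[h], xh @ p.w_k[h], xh @ p.w_v[h]
        att = np.zeros((L, L))
        for i in range(L):
            logits = np.array([q[i] @ k[j] for j in range(L)]) / np.sqrt(p.d_att)
            e = np.exp(logits - logits.max())
            att[i] = e / e.sum()
        z_heads.append(att @ v)
        w_heads.append(att)
    return np.concatenate(z_heads, axis=-1), np.stack(w_heads)


def naive_region_stretch(f, n):
    L, _, c = f.shape
    half = n // 2
    out = np.zeros((L, L, c, n * n))
    mask = np.zeros((L, L, n * n), dtype=bool)
    for i in range(L):
        for j in range(L):
            for w in range(n * n):
                dr, dc = w // n - half, w % n - half
                r, s = i + dr, j + dc
                if 0 <= r < L and 0 <= s < L:
                    out[i, j, :, w] = f[r, s, :]
                    mask[i, j, w] = True
    return out, mask


def naive_regional_attention(f, p):
    L, _, c = f.shape
    n, n2 = p.n, p.n * p.n
    stretched, mask = naive_region_stretch(f, n)
    out_heads = []
    weights = np.zeros((L, L, p.n_heads, n2))
    for h in range(p.n_heads):
        out_h = np.zeros((L, L, p.d))
        for i in range(L):
            for j in range(L):
                q = f[i, j, :] @ p.w_q[h]
                keys = stretched[i, j].T @ p.w_k[h]     # (n2, d)
                vals = stretched[i, j].T @ p.w_v[h]
                logits = keys @ q / np.sqrt(p.d)
                logits[~mask[i, j]] = -np.inf
                e = np.exp(logits - logits[mask[i, j]].max())
                e[~mask[i, j]] = 0.0
                w = e / e.sum()
                weights[i, j, h] = w
                out_h[i, j] = w @ vals
        out_heads.append(out_h)
    return (np.concatenate(out_heads, axis=-1) @ p.w_out + p.b_out), weights


# ---------------------------------------------------------------------------
# Sequence attention

def test_attention_1d_matches_loop_oracle(rng):
    for _ in range(10):
        L, d_in, heads, d_att = (int(rng.integers(2, 9)), int(rng.integers(2, 7)),
                                 int(rng.integers(1, 4)), int(rng.integers(2, 5)))
        p = init_attention1d_params(d_in, heads, d_att, rng)
        x = rng.normal(size=(L, d_in))
        z, w = multihead_attention_1d(x, p)
        z0, w0 = naive_attention_1d(x, p)
        assert np.abs(z - z0).max() < 1e-6
        assert np.abs(w.w_att - w0).max() < 1e-6


def test_zero_query_gives_uniform_attention(rng):
    p = init_attention1d_params(5, 2, 3, rng)
    p = Attention1DParams(w_in=p.w_in, b_in=p.b_in,
                          w_q=np.zeros_like(p.w_q), w_k=p.w_k, w_v=p.w_v)
    L = 6
    z, w = multihead_attention_1d(rng.normal(size=(L, 5)), p)
    assert np.abs(w.w_att - 1.0 / L).max() < 1e-12
    # uniform rows average V identically, so every output row is the same
    for h in range(2):
        zh = z[:, h * 3:(h + 1) * 3]
        assert np.abs(zh - zh.mean(axis=0)).max() < 1e-9


def test_attention_rows_sum_to_one(rng):
    p = init_attention1d_params(6, 4, 4, rng)
    _, w = multihead_attention_1d(rng.normal(size=(11, 6)), p)
    assert np.abs(w.w_att.sum(axis=-1) - 1.0).max() < 1e-10


def test_attention_rejects_nonfinite_input(rng):
    p = init_attention1d_params(4, 1, 2, rng)
    x = np.full((3, 4), np.nan)
    with pytest.raises(ValueError):
        multihead_attention_1d(x, p)


def test_attention_permutation_covariance(rng):
    """No positional encoding: permuting rows of X permutes Z rows and
    conjugates the attention weights."""
    p = init_attention1d_params(5, 2, 3, rng)
    x = rng.normal(size=(7, 5))
    perm = rng.permutation(7)
    z, w = multihead_attention_1d(x, p)
    zp, wp = multihead_attention_1d(x[perm], p)
    assert np.abs(zp - z[perm]).max() < 1e-10
    assert np.abs(wp.w_att - w.w_att[:, perm][:, :, perm]).max() < 1e-10


# ---------------------------------------------------------------------------
# Tiling

def test_tile_definition():
    z = np.array([[1.0], [2.0]])  # L=2, d=1
    out = tile_1d_to_2d(z)
    assert out.shape == (2, 2, 2)
    assert tuple(out[0, 1]) == (1.0, 2.0)
    assert tuple(out[1, 0]) == (2.0, 1.0)
    assert tuple(out[0, 0]) == (1.0, 1.0)


def test_tile_swap_symmetry(rng):
    z = rng.normal(size=(5, 3))
    out = tile_1d_to_2d(z)
    swapped = np.concatenate([out[:, :, 3:], out[:, :, :3]], axis=-1)
    assert np.array_equal(out.transpose(1, 0, 2), swapped)


# ---------------------------------------------------------------------------
# Region stretching

def test_region_stretch_paper_shape():
    out, mask = region_stretch(np.zeros((10, 10, 32)), 5)
    assert out.shape == (10, 10, 32, 25)
    assert mask.shape == (10, 10, 25)


def test_region_stretch_constant_input_window_geometry():
    v = 3.5
    out, mask = region_stretch(np.full((8, 8, 1), v), 5)
    # interior cell: all 25 entries equal v
    assert np.all(out[4, 4, 0] == v)
    # corner cell: exactly 9 in-bounds entries (3x3 overlap), 16 zeros
    corner = out[0, 0, 0]
    assert (corner == v).sum() == 9 and (corner == 0).sum() == 16
    assert mask[0, 0].sum() == 9 and mask[4, 4].sum() == 25


def test_region_stretch_matches_gather_oracle(rng):
    f = rng.normal(size=(6, 6, 2))
    out, mask = region_stretch(f, 3)
    out0, mask0 = naive_region_stretch(f, 3)
    assert np.array_equal(out, out0)
    assert np.array_equal(mask, mask0)


def test_region_stretch_rejects_even_window(rng):
    with pytest.raises(ValueError):
        region_stretch(rng.normal(size=(4, 4, 1)), 4)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000), st.sampled_from([1, 3, 5]))
def test_region_stretch_linearity(seed, n):
    r = np.random.default_rng(seed)
    f, g = r.normal(size=(5, 5, 2)), r.normal(size=(5, 5, 2))
    a, b = r.normal(), r.normal()
    lhs, _ = region_stretch(a * f + b * g, n)
    f_s, _ = region_stretch(f, n)
    g_s, _ = region_stretch(g, n)
    assert np.abs(lhs - (a * f_s + b * g_s)).max() < 1e-9


# ---------------------------------------------------------------------------
# Regional attention

def test_regional_attention_matches_loop_oracle(rng):
    for _ in range(6):
        L, c, heads, d = (int(rng.integers(3, 7)), int(rng.integers(2, 5)),
                          int(rng.integers(1, 3)), int(rng.integers(2, 5)))
        p = init_regional_attention_params(c, heads, d, c, 3, rng)
        f = rng.normal(size=(L, L, c))
        out, w = regional_attention(f, p)
        out0, w0 = naive_regional_attention(f, p)
        assert np.abs(out - out0).max() < 1e-6
        assert np.abs(w.weights - w0).max() < 1e-6


def test_regional_attention_masked_softmax_contract(rng):
    p = init_regional_attention_params(3, 2, 4, 3, 5, rng)
    _, w = regional_attention(rng.normal(size=(6, 6, 3)), p)
    sums = w.weights.sum(axis=-1)
    assert np.abs(sums - 1.0).max() < 1e-10
    oob = ~np.broadcast_to(w.inbounds[:, :, None, :], w.weights.shape)
    assert (w.weights[oob] == 0.0).all()


def test_uniform_logits_average_window(rng):
    """Zero query map -> interior positions output the unweighted mean of
    their window values (before the head projection)."""
    c, n = 3, 3
    p = init_regional_attention_params(c, 1, 2, c, n, rng)
    p.w_q[:] = 0.0
    f = rng.normal(size=(7, 7, c))
    _, w = regional_attention(f, p)
    interior = w.weights[n // 2:-(n // 2), n // 2:-(n // 2)]
    assert np.abs(interior - 1.0 / (n * n)).max() < 1e-12
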