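"""Residue importance, permutation ablation, Φ-value comparison."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

import contactattn as ca
from contactattn.attention import Attention1DWeights, RegionalAttentionWeights
from contactattn.features import ContactMap, FeatureSet, PlmTensor, Pssm
from contactattn.interpretation import (
    PhiProfile, permutation_ablation, phi_compare, regional_importance,
    regional_score_map, select_centers, sequence_importance,
    sequence_importance_per_head, n_true_positives,
)
from contactattn.network import ModelConfig, build_model, symmetrize
from contactattn.nn.modules import window_inbounds_mask


def random_row_stochastic(rng, heads, L):
    w = rng.uniform(size=(heads, L, L))
    return Attention1DWeights(w_att=w / w.sum(axis=-1, keepdims=True))


def random_regional_weights(rng, L, heads, n):
    inb = window_inbounds_mask(L, n)
    w = rng.uniform(size=(L, L, heads, n * n))
    w *= inb[:, :, None, :]
    return RegionalAttentionWeights(
        weights=w / w.sum(axis=-1, keepdims=True), inbounds=inb)


# ---------------------------------------------------------------------------
# Sequence importance

def test_uniform_weights_give_unit_importance():
    L = 7
    w = Attention1DWeights(w_att=np.full((3, L, L), 1.0 / L))
    assert np.abs(sequence_importance(w) - 1.0).max() < 1e-12


def test_importance_sums_to_length(rng):
    w = random_row_stochastic(rng, 4, 15)
    assert abs(sequence_importance(w).sum() - 15.0) < 1e-9


def test_importance_matches_loop_oracle(rng):
    w = random_row_stochastic(rng, 2, 6)
    imp = sequence_importance(w)
    for j in range(6):
        expected = sum(np.mean([w.w_att[h, i, j] for h in range(2)])
                       for i in range(6))
        assert abs(imp[j] - expected) < 1e-12
    per_head = sequence_importance_per_head(w)
    assert per_head.shape == (2, 6)
    assert np.allclose(per_head.mean(axis=0), imp)


# ---------------------------------------------------------------------------
# Regional score map

def test_uniform_regional_received_attention():
    """Uniform in-bounds weights: interior cells receive exactly 1."""
    L, n = 8, 3
    inb = window_inbounds_mask(L, n)
    w = inb[:, :, None, :].astype(float)
    w = w / w.sum(axis=-1, keepdims=True)
    smap = regional_score_map(
        RegionalAttentionWeights(weights=np.repeat(w, 2, axis=2), inbounds=inb))
    interior = smap[n - 1:-(n - 1), n - 1:-(n - 1)]
    assert np.abs(interior - 1.0).max() < 1e-12
    assert smap[0, 0] < 1.0  # border cells receive less


def test_received_mass_conservation(rng):
    L = 9
    w = random_regional_weights(rng, L, 3, 5)
    assert abs(regional_score_map(w).sum() - L * L) < 1e-8


def test_score_map_matches_quadruple_loop_oracle(rng):
    L, heads, n = 6, 2, 3
    w = random_regional_weights(rng, L, heads, n)
    smap = regional_score_map(w)
    expected = np.zeros((L, L))
    half = n // 2
    for i, j, widx in itertools.product(range(L), range(L), range(n * n)):
        r, s = i + widx // n - half, j + widx % n - half
        if 0 <= r < L and 0 <= s < L:
            expected[r, s] += w.weights[i, j, :, widx].mean()
    assert np.abs(smap - expected).max() < 1e-12


def test_regional_importance_hand_case():
    smap = np.array([[1.0, 2.0, 0.0],
                     [0.0, 1.0, 1.0],
                     [2.0, 0.0, 2.0]])
    imp = regional_importance(smap)
    rows = np.array([3, 2, 4]) / 9
    cols = np.array([3, 3, 3]) / 9
    expected = (rows + cols) / (rows + cols).sum()
    assert np.abs(imp - expected).max() < 1e-12
    assert abs(imp.sum() - 1.0) < 1e-12


def test_symmetric_map_importance_proportional_to_row_sums(rng):
    m = rng.uniform(size=(6, 6))
    smap = m + m.T
    imp = regional_importance(smap)
    rows = smap.sum(axis=1)
    assert np.abs(imp - rows / rows.sum()).max() < 1e-12


# ---------------------------------------------------------------------------
# Center selection

def make_pred_true(rng, L=40):
    true_v = (rng.uniform(size=(L, L)) < 0.12).astype(float)
    true_v = np.triu(true_v, 1) + np.triu(true_v, 1).T
    true = ContactMap(values=true_v, kind="binary")
    pred_v = np.clip(true_v * 0.6 + rng.uniform(size=(L, L)) * 0.5, 0, 1)
    pred = symmetrize(ContactMap(values=pred_v, kind="probability"))
    return pred, true


def test_select_centers_matches_sort_oracle(rng):
    pred, true = make_pred_true(rng)
    smap = rng.uniform(size=(40, 40))
    k = 4
    chosen = select_centers(smap, pred, true, k, "highest", "TP")
    from contactattn.interpretation import _outcome_groups
    cells = list(zip(*np.nonzero(_outcome_groups(pred, true)["TP"])))
    oracle = sorted(cells, key=lambda c: (-smap[c], c[0], c[1]))[:k]
    assert chosen == [(int(i), int(j)) for i, j in oracle]


def test_highest_and_lowest_disjoint(rng):
    pred, true = make_pred_true(rng)
    smap = rng.uniform(size=(40, 40))  # strictly ordered w.p. 1
    hi = set(select_centers(smap, pred, true, 3, "highest", "TN"))
    lo = set(select_centers(smap, pred, true, 3, "lowest", "TN"))
    assert not hi & lo


def test_select_centers_validation(rng):
    pred, true = make_pred_true(rng)
    smap = rng.uniform(size=(40, 40))
    with pytest.raises(ValueError):
        select_centers(smap, pred, true, 0, "highest", "TP")
    with pytest.raises(ValueError):
        select_centers(smap, pred, true, 2, "median", "TP")
    with pytest.raises(ValueError):
        select_centers(smap, pred, true, 2, "highest", "XX")


# ---------------------------------------------------------------------------
# Permutation ablation

def test_constant_channel_window_is_identity(rng):
    """Permuting cells whose channel vectors are constant changes nothing."""
    L = 30
    model = build_model(ModelConfig.tiny("regional"))
    plm = rng.normal(size=(L, L, 16))
    center = (5, 27)
    for c0, c1 in (center, center[::-1]):
        for i in range(c0 - 1, c0 + 2):
            for j in range(c1 - 1, c1 + 2):
                plm[i, j, :] = plm[i, j, 0]  # constant across channels
    plm = (plm + plm.transpose(1, 0, 2)) / 2
    # re-impose constancy after symmetrization
    for c0, c1 in (center, center[::-1]):
        for i in range(c0 - 1, c0 + 2):
            for j in range(c1 - 1, c1 + 2):
                plm[i, j, :] = plm[i, j, 0]
    fs = FeatureSet(pssm=Pssm(values=rng.uniform(size=(L, 20))),
                    plm=PlmTensor(values=plm))
    truth = (rng.uniform(size=(L, L)) < 0.1).astype(float)
    truth = np.triu(truth, 1) + np.triu(truth, 1).T
    true = ContactMap(values=truth, kind="binary")
    res = permutation_ablation(model, fs, true, [center], m=3, seed=0)
    assert res.delta_precision[0] == 0.0
    assert res.delta_tp[0] == 0.0


def test_empty_center_list_returns_zero_deltas(rng, small_dataset):
    _, fs, true = small_dataset[0]
    model = build_model(ModelConfig.tiny("regional"))
    res = permutation_ablation(model, fs, true, [], m=3, seed=1)
    assert res.mean_delta_precision == 0.0
    assert len(res.centers) == 0


@pytest.mark.parametrize("m", [1, 3, 5])
def test_supported_region_sizes(rng, small_dataset, m):
    _, fs, true = small_dataset[0]
    model = build_model(ModelConfig.tiny("regional"))
    res = permutation_ablation(model, fs, true, [(8, 15)], m=m, seed=2)
    assert res.region_size == m and len(res.centers) == 1


def test_ablation_center_bounds(small_dataset):
    _, fs, true = small_dataset[0]
    model = build_model(ModelConfig.tiny("regional"))
    with pytest.raises(ValueError):
        permutation_ablation(model, fs, true, [(99, 99)], m=3)
    with pytest.raises(ValueError):
        permutation_ablation(model, fs, true, [(1, 1)], m=2)


def test_k_equals_top_l5_true_positive_count(rng):
    pred, true = make_pred_true(rng)
    k = n_true_positives(pred, true)
    from contactattn.evaluation import top_pairs
    expected = sum(true.values[i, j] > 0.5 for i, j in top_pairs(pred, n=5))
    assert k == expected


# ---------------------------------------------------------------------------
# Φ-value comparison

def test_phi_identity_gives_r_one(rng):
    phi_vals = rng.uniform(size=30)
    phi = PhiProfile(values=phi_vals)
    p, r = phi_compare(phi_vals.copy(), phi)
    assert abs(r - 1.0) < 1e-12


def test_peak_dominance_yields_minimal_exact_p():
    """All peak importances above all others: exact one-sided rank-sum
    minimum for those group sizes."""
    L = 20
    phi_vals = np.zeros(L)
    phi_vals[10] = 1.0   # peak region [7, 14) with half-width 3
    phi = PhiProfile(values=phi_vals)
    importance = np.zeros(L)
    importance[7:14] = np.linspace(2, 3, 7)
    outside = np.linspace(0, 1, 13)
    importance[:7] = outside[:7]
    importance[14:] = outside[7:]
    p, _ = phi_compare(importance, phi)
    n1, n2 = 7, 13
    # exact enumeration: the observed arrangement is the single most extreme
    from math import comb
    assert abs(p - 1.0 / comb(n1 + n2, n1)) < 1e-9


def test_phi_permutation_null_is_calibrated(rng):
    """Importance independent of Φ: p-values roughly uniform."""
    L = 40
    phi = PhiProfile(values=rng.uniform(size=L))
    ps = []
    for _ in range(300):
        imp = rng.permutation(rng.uniform(size=L))
        p, _ = phi_compare(imp, phi)
        ps.append(p)
    ps = np.array(ps)
    # uniformity: KS distance small and no inflation at the 10% level
    assert stats.kstest(ps, "uniform").pvalue > 1e-3
    assert abs((ps < 0.1).mean() - 0.1) < 0.05


def test_phi_from_text_and_validation(tmp_path, rng):
    path = tmp_path / "phi.txt"
    path.write_text("1 0.2\n3 0.8\n5 0.4\n7 0.9\n9 0.1\n11 0.3\n13 0.5\n")
    phi = PhiProfile.from_text(path)
    assert len(phi.values) == 13
    assert phi.mask.sum() == 7
    assert phi.peak_region[0] <= 6 < phi.peak_region[1]
    with pytest.raises(ValueError):
        PhiProfile(values=np.full(5, np.nan))
    with pytest.raises(ValueError):
        phi_compare(np.zeros(10), phi)
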