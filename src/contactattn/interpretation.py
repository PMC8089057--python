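"""Attention-based interpretability.

Three procedures connect attention weights to fold-determining residues:

* **Residue importance.** The sequence-attention matrix is row-stochastic —
  entry (i, j) is the importance of residue j to residue i — so its column
  sums (after averaging the heads) score each residue's overall importance
  and sum to L. For regional attention, every window distribution is folded
  back onto the map to give each cell the total attention it *receives*; the
  normalized row and column sums of that received-attention map are combined
  into a per-residue profile that sums to 1.

* **Permutation ablation.** Input feature cells around chosen map locations
  (the k highest- or lowest-attention cells within a prediction outcome
  group, k = the target's count of top-L/5 true positives) are perturbed by
  shuffling each cell's channel vector inside an m x m window; the drop in
  top-L/5 precision after re-prediction measures how much information those
  locations carried.

* **Φ-value comparison.** Importance profiles are compared with experimental
  Φ-values: a one-sided rank-sum test of importance inside vs outside the
  highest-Φ peak region, and the Pearson correlation along the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .attention import (
    Attention1DWeights, RegionalAttentionWeights, AttentionRecord,
)
from .features import ContactMap, FeatureSet, PlmTensor, range_mask
from .evaluation import top_pairs, top_ln_precision
from .network import SequenceModule, RegionalModule, symmetrize

__all__ = [
    "PhiProfile", "AblationResult", "sequence_importance",
    "sequence_importance_per_head", "regional_score_map",
    "regional_importance", "select_centers", "permutation_ablation",
    "phi_compare",
]


@dataclass
class PhiProfile:
    """Per-residue experimental Φ-values with a missing-value mask.

    Φ is the ratio of the mutation-induced stability change of the folding
    transition-state ensemble to that of the native state; peaks mark
    residues whose interactions are already formed in the transition state.
    """

    values: np.ndarray
    mask: np.ndarray | None = None          # True where measured
    peak_region: tuple[int, int] | None = None  # half-open [start, stop)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("all Φ-values are missing")
        if self.peak_region is None:
            self.peak_region = self.find_peak()
        lo, hi = self.peak_region
        if not (0 <= lo < hi <= len(self.values)):
            raise ValueError("peak region out of bounds")

    def find_peak(self, half_width: int = 3) -> tuple[int, int]:
        """Contiguous window around the argmax of the measured Φ-values."""
        vals = np.where(self.mask, self.values, -np.inf)
        center = int(np.argmax(vals))
        return max(0, center - half_width), min(len(self.values),
                                                center + half_width + 1)

    @classmethod
    def from_text(cls, path: str | Path) -> "PhiProfile":
        """Two-column text: 1-based residue index, Φ-value."""
        raw = np.loadtxt(path, ndmin=2)
        L = int(raw[:, 0].max())
        values = np.full(L, np.nan)
        values[raw[:, 0].astype(int) - 1] = raw[:, 1]
        return cls(values=values)


@dataclass
class AblationResult:
    """Per-center effect of permuting an m x m input region."""

    centers: list[tuple[int, int]]
    delta_precision: np.ndarray   # per center: permuted - baseline top-L/5
    delta_tp: np.ndarray          # per center: change in true-positive count
    group: str                    # TP_High | TP_Low | TN_High | TN_Low | custom
    region_size: int
    k: int

    @property
    def mean_delta_precision(self) -> float:
        return float(self.delta_precision.mean()) if len(self.centers) else 0.0


# ---------------------------------------------------------------------------
# Importance profiles

def sequence_importance(w: Attention1DWeights) -> np.ndarray:
    """Column sums of the head-averaged attention matrix; sums to L."""
    return w.w_att.mean(axis=0).sum(axis=0)


def sequence_importance_per_head(w: Attention1DWeights) -> np.ndarray:
    """(n_heads, L) per-head column-sum profiles."""
    return w.w_att.sum(axis=1)


def regional_score_map(w: RegionalAttentionWeights) -> np.ndarray:
    """Fold window distributions back onto the map: received attention.

    Entry (p, q) accumulates, over every center whose window covers (p, q)
    and averaged over heads, the weight that center assigns to the cell.
    Total received mass is L^2 (each center distributes exactly one unit).
    """
    L, n = w.length, w.n
    p = n // 2
    avg = w.weights.mean(axis=2)          # (L, L, n2)
    out = np.zeros((L + 2 * p, L + 2 * p))
    for widx in range(n * n):
        dr, dc = widx // n, widx % n
        out[dr:dr + L, dc:dc + L] += avg[:, :, widx]
    return out[p:p + L, p:p + L]


def regional_importance(score_map: np.ndarray) -> np.ndarray:
    """Normalized row sums plus normalized column sums, rescaled to sum 1."""
    score_map = np.asarray(score_map, dtype=np.float64)
    rows = score_map.sum(axis=1)
    cols = score_map.sum(axis=0)
    imp = rows / rows.sum() + cols / cols.sum()
    return imp / imp.sum()


# ---------------------------------------------------------------------------
# Permutation ablation

def _outcome_groups(pred: ContactMap, true: ContactMap
                    ) -> dict[str, np.ndarray]:
    """Long-range upper-triangle cells split by top-L/5 prediction outcome."""
    L = pred.length
    band = np.triu(range_mask(L, "long"))
    if true.validity is not None:
        band &= true.validity
    selected = np.zeros((L, L), dtype=bool)
    for i, j in top_pairs(pred, n=5, range_name="long"):
        selected[i, j] = True
    truth = true.values > 0.5
    return {
        "TP": band & selected & truth,
        "FP": band & selected & ~truth,
        "TN": band & ~selected & ~truth,
        "FN": band & ~selected & truth,
    }


def select_centers(score_map: np.ndarray, pred: ContactMap, true: ContactMap,
                   k: int, which: str = "highest", group: str = "TP"
                   ) -> list[tuple[int, int]]:
    """The k extreme-attention cells within one prediction-outcome group.

    ``k`` conventionally equals the target's count of top-L/5 true positives;
    ``which`` picks the highest- or lowest-attention cells; ties are broken
    by ascending (i, j).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if which not in ("highest", "lowest"):
        raise ValueError("which must be 'highest' or 'lowest'")
    masks = _outcome_groups(pred, true)
    if group not in masks:
        raise ValueError(f"group must be one of {sorted(masks)}")
    iu, ju = np.nonzero(masks[group])
    scores = np.asarray(score_map, dtype=np.float64)[iu, ju]
    key = -scores if which == "highest" else scores
    order = np.lexsort((ju, iu, key))
    return [(int(iu[o]), int(ju[o])) for o in order[:k]]


def n_true_positives(pred: ContactMap, true: ContactMap) -> int:
    """Count of true contacts among the top-L/5 long-range predictions."""
    return sum(true.values[i, j] > 0.5
               for i, j in top_pairs(pred, n=5, range_name="long"))


def permutation_ablation(model: SequenceModule | RegionalModule,
                         fs: FeatureSet, true: ContactMap,
                         centers: list[tuple[int, int]], m: int = 3,
                         seed: int = 0, group: str = "custom",
                         baseline: ContactMap | None = None) -> AblationResult:
    """Permute the 2D input around each center and measure the effect.

    For each center independently, the channel vector of every coevolution
    cell inside the m x m window is shuffled (a seeded permutation per cell;
    a channel-wise shuffle so that even a 1 x 1 region is perturbed), the
    model re-predicts, and the change in top-L/5 long-range precision and
    true-positive count relative to the unperturbed prediction is recorded.
    Because predicted maps are symmetrized before ranking, the mirrored
    window around (j, i) is permuted together with the window around (i, j):
    both carry the same residue pair's features.
    """
    if m % 2 == 0:
        raise ValueError("region size m must be odd")
    L = fs.length
    if baseline is None:
        baseline = symmetrize(model.predict(fs).contacts)
    base_prec = top_ln_precision(baseline, true, "long", 5)
    base_tp = n_true_positives(baseline, true)
    rng = np.random.default_rng(seed)
    half = m // 2
    d_prec = np.zeros(len(centers))
    d_tp = np.zeros(len(centers))
    for c_idx, (ci, cj) in enumerate(centers):
        if not (0 <= ci < L and 0 <= cj < L):
            raise ValueError(f"center {(ci, cj)} out of bounds")
        plm = fs.plm.values.copy()
        cells = set()
        for c0, c1 in ((ci, cj), (cj, ci)):
            for i in range(max(0, c0 - half), min(L, c0 + half + 1)):
                for j in range(max(0, c1 - half), min(L, c1 + half + 1)):
                    cells.add((i, j))
        for i, j in sorted(cells):
            plm[i, j, :] = plm[i, j, rng.permutation(plm.shape[2])]
        perturbed = FeatureSet(pssm=fs.pssm,
                               plm=PlmTensor(values=plm),
                               contacts=fs.contacts)
        pred = symmetrize(model.predict(perturbed).contacts)
        prec = top_ln_precision(pred, true, "long", 5)
        d_prec[c_idx] = (prec or 0.0) - (base_prec or 0.0)
        d_tp[c_idx] = n_true_positives(pred, true) - base_tp
    return AblationResult(centers=list(centers), delta_precision=d_prec,
                          delta_tp=d_tp, group=group, region_size=m,
                          k=len(centers))


# ---------------------------------------------------------------------------
# Φ-value comparison

def phi_compare(importance: np.ndarray, phi: PhiProfile
                ) -> tuple[float, float]:
    """(one-sided rank-sum p, Pearson r) of importance against Φ-values.

    The rank-sum test asks whether importance inside the highest-Φ peak
    region exceeds importance elsewhere (missing residues excluded); the
    Pearson correlation is taken over all measured residues.
    """
    importance = np.asarray(importance, dtype=np.float64)
    if importance.shape != phi.values.shape:
        raise ValueError("importance/Φ length mismatch")
    lo, hi = phi.peak_region
    region = np.zeros(len(importance), dtype=bool)
    region[lo:hi] = True
    inside = importance[region & phi.mask]
    outside = importance[~region & phi.mask]
    if len(inside) < 3 or len(outside) < 3:
        raise ValueError("need at least 3 measured residues on each side")
    pooled = np.concatenate([inside, outside])
    method = "exact" if len(np.unique(pooled)) == len(pooled) else "auto"
    _, p_value = stats.mannwhitneyu(inside, outside, alternative="greater",
                                    method=method)
    r, _ = stats.pearsonr(importance[phi.mask], phi.values[phi.mask])
    return float(p_value), float(r)
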