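"""CASP-style contact scoring.

Precision of the top L/n ranked pairs (n = 1, 2, 5) within a sequence
separation band, pooled ROC / precision-recall curves over long-range pairs,
and the union-of-top-L/5 subset restriction used to compare models on their
confident predictions.

Only unordered pairs i < j are ranked (maps are symmetrized first); ties in
score are broken by ascending (i, j); the selection depth is floor(L/n) with
a minimum of 1. Pairs without defined ground truth (unresolved residues) are
excluded from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import ContactMap, range_mask, SEPARATION_RANGES

__all__ = [
    "top_ln_precision", "ranked_pairs", "top_pairs", "roc_pr", "RocPrResult",
    "union_top_subset", "evaluate_dataset", "EvalResult", "contact_density",
    "pair_set_mask",
]


def ranked_pairs(pred: ContactMap, range_name: str = "long"
                 ) -> list[tuple[int, int, float]]:
    """Upper-triangle pairs in the band, sorted by descending score."""
    L = pred.length
    mask = np.triu(range_mask(L, range_name))
    if pred.validity is not None:
        mask &= pred.validity
    iu, ju = np.nonzero(mask)
    scores = pred.values[iu, ju]
    order = np.lexsort((ju, iu, -scores))
    return [(int(iu[o]), int(ju[o]), float(scores[o])) for o in order]


def top_pairs(pred: ContactMap, n: int = 5, range_name: str = "long"
              ) -> list[tuple[int, int]]:
    """The top floor(L/n) (minimum 1) pairs of the band by score."""
    k = max(1, pred.length // n)
    return [(i, j) for i, j, _ in ranked_pairs(pred, range_name)[:k]]


def top_ln_precision(pred: ContactMap, true: ContactMap,
                     range_name: str = "long", n: int = 5) -> float | None:
    """Fraction of true contacts among the top floor(L/n) ranked pairs.

    Returns None when the band holds no scorable pairs (short protein), so
    the caller can exclude the target from dataset means.
    """
    if n < 1:
        raise ValueError("divisor n must be >= 1")
    if pred.length != true.length:
        raise ValueError("prediction/truth length mismatch")
    restricted = ContactMap(values=pred.values, kind=pred.kind,
                            validity=true.validity)
    pairs = ranked_pairs(restricted, range_name)
    if not pairs:
        return None
    k = max(1, pred.length // n)
    selected = pairs[:k]
    hits = sum(true.values[i, j] > 0.5 for i, j, _ in selected)
    return hits / len(selected)


@dataclass
class RocPrResult:
    roc_points: np.ndarray   # (m, 2): (FPR, TPR)
    roc_auc: float
    pr_points: np.ndarray    # (m, 2): (recall, precision)
    pr_auc: float
    n_pairs: int
    n_positive: int


def _pool_pairs(items, range_name: str, subset) -> tuple[np.ndarray, np.ndarray]:
    scores, labels = [], []
    for idx, (pred, true) in enumerate(items):
        L = pred.length
        mask = np.triu(range_mask(L, range_name))
        if true.validity is not None:
            mask &= true.validity
        if subset is not None:
            mask &= subset[idx]
        iu, ju = np.nonzero(mask)
        scores.append(pred.values[iu, ju])
        labels.append(true.values[iu, ju] > 0.5)
    return np.concatenate(scores), np.concatenate(labels)


def roc_pr(items: list[tuple[ContactMap, ContactMap]],
           subset: list[np.ndarray] | None = None,
           range_name: str = "long") -> RocPrResult:
    """Pooled threshold-sweep ROC and PR curves with trapezoidal areas.

    ``items`` pairs predictions with truths; ``subset`` optionally restricts
    each target to a boolean pair mask (e.g. the union of top-L/5 sets).
    """
    scores, labels = _pool_pairs(items, range_name, subset)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("pooled labels contain a single class")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # one operating point per distinct threshold
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[cut].astype(float)
    fp = (cut + 1) - tp
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    roc_auc = float(np.trapezoid(tpr, fpr))
    precision = tp / (tp + fp)
    recall = tp / n_pos
    pr_r = np.concatenate([[0.0], recall])
    pr_p = np.concatenate([[precision[0]], precision])
    pr_auc = float(np.trapezoid(pr_p, pr_r))
    return RocPrResult(
        roc_points=np.column_stack([fpr, tpr]), roc_auc=roc_auc,
        pr_points=np.column_stack([pr_r, pr_p]), pr_auc=pr_auc,
        n_pairs=len(s), n_positive=n_pos)


def union_top_subset(pred_maps: list[ContactMap], n: int = 5,
                     range_name: str = "long") -> set[tuple[int, int]]:
    """Union over models of each model's top floor(L/n) pairs in the band."""
    if not pred_maps:
        return set()
    L = pred_maps[0].length
    if any(m.length != L for m in pred_maps):
        raise ValueError("maps must share L")
    out: set[tuple[int, int]] = set()
    for m in pred_maps:
        out.update(top_pairs(m, n=n, range_name=range_name))
    return out


def pair_set_mask(pairs: set[tuple[int, int]], L: int) -> np.ndarray:
    mask = np.zeros((L, L), dtype=bool)
    for i, j in pairs:
        mask[i, j] = True
    return mask


def contact_density(true: ContactMap, range_name: str = "long") -> float | None:
    """Fraction of band pairs that are contacts (random-ranking baseline)."""
    mask = np.triu(range_mask(true.length, range_name))
    if true.validity is not None:
        mask &= true.validity
    total = int(mask.sum())
    if total == 0:
        return None
    return float((true.values[mask] > 0.5).sum() / total)


@dataclass
class EvalResult:
    """Per-target and mean top-L/n precisions (ranges x depths)."""

    per_target: pd.DataFrame    # rows: targets; columns: "<range>_L<n>"
    means: pd.Series

    def table(self) -> pd.DataFrame:
        """Mean precisions laid out as ranges x depths."""
        rows = {}
        for rng in SEPARATION_RANGES:
            rows[rng] = {f"top_L/{n}": self.means.get(f"{rng}_L{n}", np.nan)
                         for n in (5, 2, 1)}
        return pd.DataFrame(rows).T


def evaluate_dataset(preds: list[ContactMap], truths: list[ContactMap],
                     ids: list[str] | None = None,
                     ranges: tuple[str, ...] = ("short", "medium", "long"),
                     depths: tuple[int, ...] = (5, 2, 1)) -> EvalResult:
    """Score a set of targets; dataset means are unweighted per-target means,
    with undefined (no-pair) entries excluded rather than scored zero."""
    if len(preds) != len(truths):
        raise ValueError("preds and truths must align")
    ids = ids or [f"target_{k}" for k in range(len(preds))]
    records = {}
    for tid, pred, true in zip(ids, preds, truths):
        row = {}
        for rng in ranges:
            for n in depths:
                row[f"{rng}_L{n}"] = top_ln_precision(pred, true, rng, n)
        records[tid] = row
    table = pd.DataFrame.from_dict(records, orient="index").astype(float)
    return EvalResult(per_target=table, means=table.mean(axis=0, skipna=True))
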