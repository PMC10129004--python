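"""Classification metrics suited to small unbalanced multi-class problems.

Balanced accuracy (mean per-class recall), multi-class log loss, and a
prior-weighted one-vs-one AUC. All operate on a probability matrix whose
columns follow a stated class order, or on a confusion matrix with reference
classes on the rows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "confusion_matrix",
    "row_normalize",
    "balanced_accuracy",
    "accuracy",
    "multiclass_log_loss",
    "multiclass_auc",
]

_PROB_TOL = 1e-6
_CLIP = 1e-15


def confusion_matrix(truth, pred, classes=None) -> pd.DataFrame:
    """Count matrix with reference classes on rows, predictions on columns."""
    if classes is None:
        classes = np.unique(np.concatenate([np.asarray(truth), np.asarray(pred)]))
    classes = list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=float)
    for t, p in zip(truth, pred):
        cm[idx[t], idx[p]] += 1
    return pd.DataFrame(cm, index=classes, columns=classes)


def row_normalize(cm: pd.DataFrame) -> pd.DataFrame:
    """Rates per reference class: each row sums to 1 (empty rows stay 0)."""
    sums = cm.sum(axis=1)
    out = cm.div(sums.where(sums > 0, 1.0), axis=0)
    return out


def balanced_accuracy(cm: pd.DataFrame) -> float:
    """Mean per-class recall: average of diagonal / row sum over reference rows.

    Rows with no observations (a degenerate test draw) are excluded with a
    warning rather than contributing 0.
    """
    cm = pd.DataFrame(cm)
    sums = cm.sum(axis=1).to_numpy()
    diag = np.diag(cm.to_numpy())
    empty = sums == 0
    if empty.all():
        raise ValueError("confusion matrix has no observations")
    if empty.any():
        warnings.warn(
            f"excluding empty reference class(es): {list(cm.index[empty])}", stacklevel=2
        )
    recalls = diag[~empty] / sums[~empty]
    return float(recalls.mean())


def accuracy(cm: pd.DataFrame) -> float:
    cm = pd.DataFrame(cm)
    return float(np.diag(cm.to_numpy()).sum() / cm.to_numpy().sum())


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    bad = np.abs(probs.sum(axis=1) - 1.0) > _PROB_TOL
    if bad.any():
        raise ValueError(
            f"{bad.sum()} probability row(s) do not sum to 1 within {_PROB_TOL}"
        )
    return probs


def multiclass_log_loss(probs: np.ndarray, truth, classes) -> float:
    """Mean negative log probability of the true class.

    Probabilities are clipped to [1e-15, 1 - 1e-15]; rows must sum to 1
    within 1e-6.
    """
    probs = _check_probs(probs)
    idx = {c: i for i, c in enumerate(classes)}
    cols = np.array([idx[t] for t in truth])
    p_true = np.clip(probs[np.arange(len(cols)), cols], _CLIP, 1 - _CLIP)
    return float(-np.mean(np.log(p_true)))


def _rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC for a binary problem; tied scores contribute 1/2."""
    r = rankdata(scores)
    n1 = int(positive.sum())
    n0 = len(scores) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("rank AUC needs both classes present")
    return float((r[positive].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def multiclass_auc(probs: np.ndarray, truth, classes) -> float:
    """Prior-weighted one-vs-one AUC.

    Every unordered class pair (i, j) contributes the symmetrized pairwise
    AUC — the mean of AUC(i vs j ranked by p_i) and AUC(j vs i ranked by
    p_j) over the rows belonging to the two classes — weighted by the
    product of the two class frequencies, so common confusions dominate the
    average. For two classes this reduces exactly to the rank (Mann-Whitney)
    AUC. Classes absent from the truth are excluded with a warning.
    """
    probs = _check_probs(probs)
    truth = np.asarray(truth)
    classes = list(classes)
    present = [c for c in classes if (truth == c).any()]
    absent = [c for c in classes if c not in present]
    if absent:
        warnings.warn(f"class(es) absent from truth excluded from AUC: {absent}", stacklevel=2)
    if len(present) < 2:
        raise ValueError("AUC requires at least two classes present in truth")
    col = {c: i for i, c in enumerate(classes)}
    total, wsum = 0.0, 0.0
    for a_i, ci in enumerate(present):
        for cj in present[a_i + 1 :]:
            mask = (truth == ci) | (truth == cj)
            is_i = truth[mask] == ci
            a_ij = _rank_auc(probs[mask, col[ci]], is_i)
            a_ji = _rank_auc(probs[mask, col[cj]], ~is_i)
            w = float(is_i.sum()) * float((~is_i).sum())
            total += w * 0.5 * (a_ij + a_ji)
            wsum += w
    return float(total / wsum)
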