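"""Repeated-holdout evaluation, nested permutation baselines, and
permutation feature importance.

The evaluation protocol for small corpora: average metrics over many
(default 100) stratified 80/20 train/test splits, standardizing on the
training partition of each split. Chance level is estimated by a nested
permutation baseline that shuffles the predicted variable *within* the
levels of a secondary grouping variable (e.g. individual within call type),
so the null respects the corpus structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import metrics as M
from .classifiers import ClassifierSpec, EnsembleSpec, fit_predict, stack
from .table import FeatureTable, standardize

__all__ = [
    "MetricsReport",
    "PermutationNull",
    "stratified_split",
    "repeated_holdout",
    "permutation_null",
    "permutation_importance",
]

ALL_METRICS = ("log_loss", "auc", "bac", "acc")


@dataclass
class MetricsReport:
    per_rep: pd.DataFrame                 # one row per repetition, metric columns
    mean_confusion: pd.DataFrame          # averaged row-normalized confusion matrix
    provenance: dict = field(default_factory=dict)

    @property
    def mean(self) -> pd.Series:
        return self.per_rep.mean(axis=0)

    @property
    def sd(self) -> pd.Series:
        return self.per_rep.std(axis=0, ddof=1)

    def __repr__(self) -> str:
        stats = ", ".join(f"{k}={v:.3f}" for k, v in self.mean.items())
        return f"MetricsReport({len(self.per_rep)} reps: {stats})"


@dataclass
class PermutationNull:
    metric: str
    null_values: np.ndarray
    observed: float
    p_value: float

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))


def stratified_split(
    labels: np.ndarray | pd.Series,
    test_frac: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random per-class 80/20 split; per-class test share within +-1 call.

    Returns boolean masks (train, test) aligned with *labels*.
    """
    labels = pd.Series(np.asarray(labels))
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(labels), dtype=bool)
    for cls, idx in labels.groupby(labels).groups.items():
        idx = np.asarray(idx)
        n_test = int(round(len(idx) * test_frac))
        n_test = min(max(n_test, 1 if len(idx) >= 2 else 0), len(idx) - 1)
        chosen = rng.choice(idx, size=n_test, replace=False)
        test_mask[chosen] = True
    return ~test_mask, test_mask


def _predict(model, train, test, label, seed):
    """Dispatch a single-table or multi-table model fit."""
    if isinstance(model, EnsembleSpec):
        return stack(model, train, test, label, seed=seed)
    if isinstance(train, Mapping):
        train = train[model.feature_set] if model.feature_set in train else next(iter(train.values()))
        test = test[model.feature_set] if model.feature_set in test else next(iter(test.values()))
    return fit_predict(model, train, test, label, seed=seed)


def _score_all(probs: pd.DataFrame, truth, classes, which) -> dict:
    aligned = np.zeros((len(probs), len(classes)))
    for j, c in enumerate(probs.columns):
        aligned[:, list(classes).index(c)] = probs.to_numpy()[:, j]
    pred = np.asarray(classes)[aligned.argmax(axis=1)]
    cm = M.confusion_matrix(truth, pred, classes)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if "log_loss" in which:
            out["log_loss"] = M.multiclass_log_loss(aligned, truth, classes)
        if "auc" in which:
            out["auc"] = M.multiclass_auc(aligned, truth, classes)
        if "bac" in which:
            out["bac"] = M.balanced_accuracy(cm)
        if "acc" in which:
            out["acc"] = M.accuracy(cm)
    return out, cm


def repeated_holdout(
    table: FeatureTable | Mapping[str, FeatureTable],
    model: ClassifierSpec | EnsembleSpec,
    label: str,
    splitter: Callable[[np.ndarray, int], tuple[np.ndarray, np.ndarray]] | None = None,
    n_reps: int = 100,
    test_frac: float = 0.2,
    seed: int = 0,
    metrics: tuple[str, ...] = ALL_METRICS,
) -> MetricsReport:
    """Average metrics over repeated stratified train/test splits.

    Per repetition: draw a split (default: stratified random 80/20 on the
    label), z-score both partitions with training statistics, fit the model,
    score the requested metrics, and row-normalize the confusion matrix.
    Aggregates are means and standard deviations over repetitions; confusion
    matrices are averaged after row-normalization. A repetition whose
    training draw lost a class entirely is redrawn (at most 10 retries).
    """
    tables = table if isinstance(table, Mapping) else {getattr(table, "feature_set", "x"): table}
    ref = next(iter(tables.values()))
    y_all = np.asarray(ref.y(label))
    classes = np.unique(y_all)
    if pd.Series(y_all).value_counts().min() < 2:
        raise ValueError("every class needs at least 2 members")
    split_fn = splitter or (lambda labels, s: stratified_split(labels, test_frac, s))

    rows, cms = [], []
    for rep in range(n_reps):
        rep_seed = seed * 100_003 + rep
        for attempt in range(10):
            train_mask, test_mask = split_fn(y_all, rep_seed + 7919 * attempt)
            if set(np.unique(y_all[train_mask])) == set(classes):
                break
        else:
            raise RuntimeError("could not draw a split containing every class in training")
        ids = ref.data.index.to_numpy()
        trains, tests = {}, {}
        for tag, tab in tables.items():
            tr = tab.select_rows(ids[train_mask])
            te = tab.select_rows(ids[test_mask])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tests[tag] = standardize(te, reference=tr)
                trains[tag] = standardize(tr)
        tr_in = trains if isinstance(table, Mapping) else next(iter(trains.values()))
        te_in = tests if isinstance(table, Mapping) else next(iter(tests.values()))
        probs = _predict(model, tr_in, te_in, label, seed=rep_seed)
        scores, cm = _score_all(probs, y_all[test_mask], classes, metrics)
        rows.append(scores)
        cms.append(M.row_normalize(cm))

    per_rep = pd.DataFrame(rows)
    mean_cm = sum(cms) / len(cms)
    prov = {
        "model": getattr(model, "family", "ensemble"),
        "label": label,
        "n_reps": n_reps,
        "test_frac": test_frac,
        "seed": seed,
    }
    return MetricsReport(per_rep, mean_cm, prov)


def permutation_null(
    table: FeatureTable,
    model: ClassifierSpec | EnsembleSpec,
    pv: str,
    secondary: str | None,
    n_perm: int = 1000,
    seed: int = 0,
    test_frac: float = 0.2,
    metric: str = "bac",
) -> PermutationNull:
    """Nested permutation chance baseline.

    Each permutation shuffles the predicted variable *pv* within each level
    of the *secondary* variable (levels of size 1 are left unpermuted), then
    runs one standardize/fit/score train-test evaluation. The empirical
    p-value is the fraction of permutations performing at least as well as
    the observed run (for log loss: at most as badly); with 0 such
    permutations p = 0.
    """
    rng = np.random.default_rng(seed)
    y = pd.Series(table.y(pv), index=table.data.index)
    sec = (
        pd.Series(table.y(secondary), index=table.data.index)
        if secondary is not None
        else pd.Series("all", index=table.data.index)
    )

    def one_eval(labels: pd.Series, s: int) -> float:
        tab = FeatureTable(table.data.assign(**{pv: labels.to_numpy()}), table.feature_set)
        rep = repeated_holdout(
            tab, model, pv, n_reps=1, test_frac=test_frac, seed=s, metrics=(metric,)
        )
        return float(rep.mean[metric])

    observed = one_eval(y, seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = y.copy()
        for _, idx in sec.groupby(sec).groups.items():
            idx = list(idx)
            if len(idx) < 2:
                continue
            vals = shuffled.loc[idx].to_numpy()
            shuffled.loc[idx] = rng.permutation(vals)
        # conservation: the per-level multiset of labels is unchanged
        for _, idx in sec.groupby(sec).groups.items():
            if sorted(shuffled.loc[list(idx)]) != sorted(y.loc[list(idx)]):
                raise AssertionError("permutation broke per-level label counts")
        null[i] = one_eval(shuffled, seed + 1 + i)

    if metric == "log_loss":
        p = float(np.mean(null <= observed))
    else:
        p = float(np.mean(null >= observed))
    return PermutationNull(metric=metric, null_values=null, observed=observed, p_value=p)


def permutation_importance(
    model: ClassifierSpec | EnsembleSpec,
    train: FeatureTable,
    test: FeatureTable,
    label: str,
    metric: str = "bac",
    n_perm: int = 50,
    seed: int = 0,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature importance: mean performance drop when that feature's
    test values are shuffled, with the sd over shuffles.

    The model is fit once on the training table; each feature column of the
    test table is then permuted *n_perm* times and rescored.
    """
    from .classifiers import fit_model

    if isinstance(model, EnsembleSpec):
        raise TypeError("permutation importance applies to single-classifier specs")
    rng = np.random.default_rng(seed)
    feats = features if features is not None else test.feature_names
    missing = [f for f in feats if f not in test.feature_names]
    if missing:
        raise ValueError(f"feature(s) not in table: {missing}")
    y_all = np.asarray(train.y(label))
    classes = np.unique(y_all)
    truth = np.asarray(test.y(label))
    fitted = fit_model(model, train, label, seed=seed)

    def score(te: FeatureTable) -> float:
        probs = fitted.predict(te)
        s, _ = _score_all(probs, truth, classes, (metric,))
        return s[metric]

    baseline = score(test)
    rows = []
    for feat in feats:
        drops = np.empty(n_perm)
        for i in range(n_perm):
            shuffled = test.data.copy()
            shuffled[feat] = rng.permutation(shuffled[feat].to_numpy())
            drop = baseline - score(FeatureTable(shuffled, test.feature_set))
            drops[i] = -drop if metric == "log_loss" else drop
        rows.append({"feature": feat, "importance": drops.mean(), "sd": drops.std(ddof=1)})
    return pd.DataFrame(rows).set_index("feature")
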