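"""Classifier families, training protocols, and stacked ensembling.

Four families are benchmarked on call-type and individual-signature tasks:

* ``dfa`` — linear discriminant analysis trained on a balanced per-class
  subsample (the classical bioacoustics baseline), with a stepwise-VIF or
  PCA front-end to tame collinearity;
* ``svm`` — support-vector machine with probability outputs;
* ``xgboost`` — gradient-boosted trees;
* ``nn`` — a shallow dense network (see :mod:`sungkit._mlp`).

Class imbalance is handled with class weights inversely proportional to
class size. Hyperparameters are tuned separately from the evaluation loop
with repeated cross-validation on log loss, by a random-forest-based
sequential model-based optimizer (random search fallback). Stacked
ensembles train an L2-penalized multinomial regression super-learner on
out-of-fold base-model probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .table import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "EnsembleSpec",
    "HYPERPARAMETER_SPACES",
    "default_spec",
    "stepwise_vif_reduce",
    "balanced_subsample_size",
    "dfa_fit_predict",
    "pca_frontend_select",
    "tune",
    "fit_model",
    "FittedModel",
    "fit_predict",
    "stack",
]


@dataclass
class ClassifierSpec:
    """One classifier configuration: family, hyperparameters, weighting mode."""

    family: str
    params: dict = field(default_factory=dict)
    class_weighting: str | None = "inverse"  # w_c proportional to 1/n_c
    feature_set: str = "union"
    probability: bool = True  # svm: False skips Platt scaling (argmax one-hot output)

    def __post_init__(self) -> None:
        if self.family not in ("dfa", "svm", "xgboost", "nn"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        space = HYPERPARAMETER_SPACES.get(self.family, {})
        for name, value in self.params.items():
            rng = space.get(name)
            if rng is None:
                continue
            if isinstance(rng, tuple) and isinstance(value, (int, float)):
                lo, hi = rng
                if not (lo <= value <= hi):
                    raise ValueError(f"{self.family}.{name}={value} outside range {rng}")
            elif isinstance(rng, (list, set)) and value not in rng:
                raise ValueError(f"{self.family}.{name}={value!r} not in {rng}")


#: declared tuning ranges; power-of-two parameters are sampled on the log2 scale
HYPERPARAMETER_SPACES: dict[str, dict] = {
    "svm": {
        "kernel": ["linear", "polynomial", "radial"],
        "degree": (1, 4),
        "C": (2.0**-7, 2.0**7),
        "gamma": (2.0**-13, 2.0**5),
    },
    "nn": {
        "epochs": (25, 200),
        "n_layers": (1, 3),
        "neurons1": (5, 100),
        "neurons2": (5, 100),
        "neurons3": (5, 100),
        "dropout": (0.1, 0.5),
        "input_dropout": (0.1, 0.5),
    },
    "xgboost": {
        "rounds": (10, 1000),
        "eta": (0.01, 0.2),
        "gamma": (2.0**-20, 2.0**6),
        "max_depth": (1, 10),
        "min_child_weight": (1, 10),
        "subsample": (0.5, 1.0),
        "colsample": (0.5, 1.0),
        "alpha": (2.0**-20, 2.0**6),
    },
    "dfa": {},
}

_LOG2_PARAMS = {
    "svm": ("C", "gamma"),
    "xgboost": ("gamma", "alpha"),
    "nn": (),
    "dfa": (),
}
_INT_PARAMS = {
    "svm": ("degree",),
    "nn": ("epochs", "n_layers", "neurons1", "neurons2", "neurons3"),
    "xgboost": ("rounds", "max_depth", "min_child_weight"),
    "dfa": (),
}


def default_spec(family: str, feature_set: str = "union", **overrides) -> ClassifierSpec:
    """A sensible mid-range configuration, useful before (or without) tuning."""
    defaults = {
        "svm": {"kernel": "radial", "C": 2.0, "gamma": 2.0**-3},
        "xgboost": {
            "rounds": 200, "eta": 0.1, "gamma": 2.0**-10, "max_depth": 3,
            "min_child_weight": 1, "subsample": 0.9, "colsample": 0.9, "alpha": 2.0**-10,
        },
        "nn": {
            "epochs": 100, "n_layers": 1, "neurons1": 32,
            "dropout": 0.2, "input_dropout": 0.1,
        },
        "dfa": {},
    }[family]
    defaults.update(overrides.pop("params", {}))
    return ClassifierSpec(family=family, params=defaults, feature_set=feature_set, **overrides)


# ---------------------------------------------------------------------------
# collinearity / front-ends for DFA


def stepwise_vif_reduce(table: FeatureTable, threshold: float = 5.0) -> list[str]:
    """Drop features one at a time until every variance inflation factor is
    below *threshold*.

    At each step the feature with the largest VIF (ties: the later-listed
    column, so a perfectly duplicated column loses to its original) is
    removed and VIFs are recomputed. Returns the retained feature names.
    """
    X = table.features.to_numpy(dtype=float)
    names = list(table.feature_names)
    if len(names) < 2:
        raise ValueError("VIF reduction needs at least two features")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF regressions need more rows than features")

    def vifs(M: np.ndarray) -> np.ndarray:
        out = np.empty(M.shape[1])
        A = np.column_stack([np.ones(len(M)), M])
        for j in range(M.shape[1]):
            others = np.delete(A, j + 1, axis=1)
            yj = M[:, j]
            coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
            resid = yj - others @ coef
            ss_res = float(resid @ resid)
            ss_tot = float(((yj - yj.mean()) ** 2).sum())
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return out

    keep = list(range(len(names)))
    while len(keep) > 1:
        v = vifs(X[:, keep])
        worst = np.nanmax(v)
        if worst < threshold:
            break
        # ties broken toward the later-listed column
        worst_local = max(j for j in range(len(keep)) if v[j] == worst)
        dropped = names[keep[worst_local]]
        logger.info("stepwise VIF: dropping %s (VIF=%.3g)", dropped, worst)
        keep.pop(worst_local)
    return [names[j] for j in keep]


def balanced_subsample_size(min_class_count: int, fraction: float = 2 / 3) -> int:
    """Training draws per class for balanced DFA: floor of 2/3 the smallest class."""
    return int(np.floor(min_class_count * fraction))


def dfa_fit_predict(
    train: FeatureTable,
    test: FeatureTable,
    label: str,
    balanced_n: int | None = None,
    seed: int = 0,
    vif_threshold: float | None = None,
    n_pcs: int | None = None,
) -> pd.DataFrame:
    """Linear discriminant functions on a balanced per-class subsample.

    Exactly *balanced_n* training calls are drawn from every class (default:
    floor of 2/3 of the smallest class count) before fitting, so the prior
    is uniform regardless of corpus imbalance; posteriors are returned for
    the test rows. Optional front-ends: stepwise VIF column reduction or a
    PCA projection to *n_pcs* components fit on the training rows.
    """
    spec = ClassifierSpec(
        family="dfa",
        params={"balanced_n": balanced_n, "vif_threshold": vif_threshold, "n_pcs": n_pcs},
    )
    return fit_model(spec, train, label, seed=seed).predict(test)


def pca_frontend_select(
    train: FeatureTable,
    label: str,
    max_pcs: int,
    span: float = 2.5,
    cv: int = 5,
    seed: int = 0,
) -> int:
    """Pick the PCA component count minimizing smoothed cross-validated
    discriminant log loss.

    The raw curve (CV log loss vs number of components) is smoothed with a
    lowess regression; spans >= 1 are clamped to use every point (larger
    spans no longer move the minimum). Returns the argmin of the smoothed
    curve, ties toward fewer components.
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.model_selection import StratifiedKFold
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if max_pcs < 2:
        raise ValueError("max_pcs must be at least 2")
    X = train.X
    y = np.asarray(train.y(label))
    max_pcs = min(max_pcs, X.shape[1], len(X) - 1)
    from .metrics import multiclass_log_loss

    classes = np.unique(y)
    ks = np.arange(1, max_pcs + 1)
    losses = np.empty(len(ks))
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for i, k in enumerate(ks):
        fold_losses = []
        for tr, te in folds:
            pca = PCA(n_components=int(k), random_state=seed).fit(X[tr])
            lda = LinearDiscriminantAnalysis().fit(pca.transform(X[tr]), y[tr])
            probs_raw = lda.predict_proba(pca.transform(X[te]))
            probs = np.zeros((len(te), len(classes)))
            for j, c in enumerate(lda.classes_):
                probs[:, list(classes).index(c)] = probs_raw[:, j]
            fold_losses.append(multiclass_log_loss(probs, y[te], classes))
        losses[i] = np.mean(fold_losses)
    frac = min(1.0, span)
    smoothed = lowess(losses, ks.astype(float), frac=frac, return_sorted=False)
    return int(ks[int(np.argmin(smoothed))])


# ---------------------------------------------------------------------------
# weighting & fitting


def _class_weights(y: np.ndarray) -> dict:
    classes, counts = np.unique(y, return_counts=True)
    w = len(y) / (len(classes) * counts)
    return dict(zip(classes, w))


@dataclass
class FittedModel:
    """A fitted configuration that can score many test tables."""

    spec: ClassifierSpec
    classes: list
    _predict_proba: "callable"
    feature_columns: list[str] | None = None  # VIF-reduced columns (dfa)

    def predict(self, test: FeatureTable) -> pd.DataFrame:
        te = test.select_features(self.feature_columns) if self.feature_columns else test
        probs = np.asarray(self._predict_proba(te.X), dtype=float)
        probs = np.clip(probs, 0.0, 1.0)
        probs = probs / probs.sum(axis=1, keepdims=True)
        return pd.DataFrame(probs, index=test.data.index, columns=list(self.classes))


def fit_model(
    spec: ClassifierSpec, train: FeatureTable, label: str, seed: int = 0
) -> FittedModel:
    """Fit one configuration on the training table.

    Class weights inversely proportional to class size are applied as
    per-class misclassification costs (svm) or per-sample weights (trees,
    network) when ``spec.class_weighting == "inverse"``.
    """
    y = np.asarray(train.y(label))
    Xtr = train.X
    weights = _class_weights(y) if spec.class_weighting == "inverse" else None
    p = spec.params
    kept_cols: list[str] | None = None

    if spec.family == "svm":
        from sklearn.svm import SVC

        kernel = {"linear": "linear", "polynomial": "poly", "radial": "rbf"}[
            p.get("kernel", "radial")
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf = SVC(
                kernel=kernel,
                degree=int(p.get("degree", 3)),
                C=float(p.get("C", 1.0)),
                gamma=float(p.get("gamma", 2.0**-3)) if kernel != "linear" else "scale",
                class_weight=weights,
                probability=spec.probability,
                random_state=seed,
            )
            clf.fit(Xtr, y)
        classes = list(clf.classes_)
        if spec.probability:
            proba = clf.predict_proba
        else:  # hard predictions as a one-hot matrix (rank metrics degenerate)
            lookup = {c: i for i, c in enumerate(classes)}

            def proba(X, _clf=clf, _lookup=lookup, _k=len(classes)):
                pred = _clf.predict(X)
                out = np.zeros((len(X), _k))
                out[np.arange(len(pred)), [_lookup[v] for v in pred]] = 1.0
                return out

    elif spec.family == "xgboost":
        from xgboost import XGBClassifier

        codes, y_idx = np.unique(y, return_inverse=True)
        clf = XGBClassifier(
            n_estimators=int(p.get("rounds", 200)),
            learning_rate=float(p.get("eta", 0.1)),
            gamma=float(p.get("gamma", 0.0)),
            max_depth=int(p.get("max_depth", 3)),
            min_child_weight=float(p.get("min_child_weight", 1)),
            subsample=float(p.get("subsample", 1.0)),
            colsample_bytree=float(p.get("colsample", 1.0)),
            reg_alpha=float(p.get("alpha", 0.0)),
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
        sw = np.array([weights[c] for c in y]) if weights else None
        clf.fit(Xtr, y_idx, sample_weight=sw)
        classes, proba = list(codes), clf.predict_proba

    elif spec.family == "nn":
        from ._mlp import DenseSoftmaxNet

        n_layers = int(p.get("n_layers", 1))
        hidden = tuple(int(p.get(f"neurons{i}", 32)) for i in range(1, n_layers + 1))
        net = DenseSoftmaxNet(
            hidden=hidden,
            epochs=int(p.get("epochs", 100)),
            dropout=float(p.get("dropout", 0.2)),
            input_dropout=float(p.get("input_dropout", 0.1)),
            seed=seed,
        )
        sw = np.array([weights[c] for c in y]) if weights else None
        net.fit(Xtr, y, sample_weight=sw)
        classes, proba = list(net.classes_), net.predict_proba

    elif spec.family == "dfa":
        from sklearn.decomposition import PCA
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        # for MFCC input the per-call sd block is near-constant once
        # standardized and degrades the discriminant: use the 96 means only
        if train.feature_set == "mfcc":
            kept_cols = [c for c in train.feature_names if c.endswith(".mean")]
            train = train.select_features(kept_cols)

        rng = np.random.default_rng(seed)
        ys = pd.Series(y, index=train.data.index)
        counts = ys.value_counts()
        balanced_n = p.get("balanced_n") or balanced_subsample_size(int(counts.min()))
        if balanced_n < 1 or balanced_n > counts.min():
            raise ValueError(
                f"balanced_n={balanced_n} exceeds smallest class size {counts.min()}"
            )
        chosen: list = []
        for cls in counts.index:
            cand = ys.index[ys == cls].to_numpy()
            chosen.extend(rng.choice(cand, size=int(balanced_n), replace=False))
        sub = train.select_rows(chosen)
        if p.get("vif_threshold") is not None:
            kept_cols = stepwise_vif_reduce(sub, p["vif_threshold"])
            sub = sub.select_features(kept_cols)
        Xs = sub.X
        pca = None
        if p.get("n_pcs") is not None:
            pca = PCA(n_components=int(p["n_pcs"]), random_state=seed).fit(Xs)
            Xs = pca.transform(Xs)
        lda = LinearDiscriminantAnalysis()
        try:
            lda.fit(Xs, sub.y(label))
        except np.linalg.LinAlgError as err:  # pragma: no cover - env dependent
            raise ValueError(
                "singular within-class covariance; apply a VIF or PCA front-end"
            ) from err
        classes = list(lda.classes_)

        def proba(X, _lda=lda, _pca=pca):
            return _lda.predict_proba(_pca.transform(X) if _pca is not None else X)

    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(f"unknown family {spec.family!r}")

    return FittedModel(spec=spec, classes=classes, _predict_proba=proba, feature_columns=kept_cols)


def fit_predict(
    spec: ClassifierSpec,
    train: FeatureTable,
    test: FeatureTable,
    label: str,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit on the training table and return test-class probabilities
    (rows sum to 1; columns = sorted training classes)."""
    return fit_model(spec, train, label, seed=seed).predict(test)


# ---------------------------------------------------------------------------
# hyperparameter tuning


def _sample_params(family: str, rng: np.random.Generator) -> dict:
    space = HYPERPARAMETER_SPACES[family]
    out: dict = {}
    for name, spec_range in space.items():
        if isinstance(spec_range, list):
            out[name] = spec_range[rng.integers(len(spec_range))]
        elif name in _LOG2_PARAMS[family]:
            lo, hi = np.log2(spec_range[0]), np.log2(spec_range[1])
            out[name] = float(2.0 ** rng.uniform(lo, hi))
        elif name in _INT_PARAMS[family]:
            out[name] = int(rng.integers(spec_range[0], spec_range[1] + 1))
        else:
            out[name] = float(rng.uniform(spec_range[0], spec_range[1]))
    return out


def _encode_params(family: str, params: dict) -> np.ndarray:
    space = HYPERPARAMETER_SPACES[family]
    vec = []
    for name, spec_range in space.items():
        v = params.get(name)
        if isinstance(spec_range, list):
            vec.append(float(spec_range.index(v)) if v in spec_range else -1.0)
        elif v is None:
            vec.append(np.nan)
        elif name in _LOG2_PARAMS[family]:
            vec.append(float(np.log2(v)))
        else:
            vec.append(float(v))
    return np.nan_to_num(np.asarray(vec), nan=0.0)


def _cv_log_loss(
    family: str,
    params: dict,
    table: FeatureTable,
    label: str,
    n_splits: int,
    n_repeats: int,
    seed: int,
) -> float:
    from sklearn.model_selection import RepeatedStratifiedKFold

    from .metrics import multiclass_log_loss
    from .table import standardize

    y = np.asarray(table.y(label))
    classes = np.unique(y)
    rskf = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)
    spec = ClassifierSpec(family=family, params=params)
    losses = []
    ids = table.data.index.to_numpy()
    for fold, (tr, te) in enumerate(rskf.split(table.X, y)):
        train = table.select_rows(ids[tr])
        test = table.select_rows(ids[te])
        test = standardize(test, reference=train)
        train = standardize(train)
        probs = fit_predict(spec, train, test, label, seed=seed + fold)
        aligned = np.zeros((len(te), len(classes)))
        for j, c in enumerate(probs.columns):
            aligned[:, list(classes).index(c)] = probs.to_numpy()[:, j]
        losses.append(multiclass_log_loss(aligned, y[te], classes))
    return float(np.mean(losses))


def tune(
    table: FeatureTable,
    family: str,
    label: str,
    budget: int = 25,
    cv: tuple[int, int] = (5, 5),
    seed: int = 0,
    tuner: str = "mbo",
) -> ClassifierSpec:
    """Search the family's hyperparameter space for the configuration
    minimizing repeated-cross-validated log loss.

    ``cv = (n_splits, n_repeats)`` controls the repeated stratified K-fold
    used to score each configuration; tuning is decoupled from the
    100-repetition performance evaluation. The default tuner is a
    random-forest surrogate optimizer with a lower-confidence-bound infill;
    ``tuner="random"`` (or a budget below 5) falls back to random search.
    """
    if family == "dfa":
        return ClassifierSpec(family="dfa", params={})
    rng = np.random.default_rng(seed)
    n_splits, n_repeats = cv
    y = pd.Series(table.y(label))
    if y.value_counts().min() < n_splits:
        raise ValueError(f"every class needs >= {n_splits} members for {n_splits}-fold CV")
    if budget < 5:
        warnings.warn("budget < 5: using pure random search", stacklevel=2)
        tuner = "random"

    evaluated: list[tuple[dict, float]] = []

    def score(params: dict) -> float:
        loss = _cv_log_loss(family, params, table, label, n_splits, n_repeats, seed)
        evaluated.append((params, loss))
        return loss

    n_init = budget if tuner == "random" else max(5, budget // 3)
    for _ in range(min(n_init, budget)):
        score(_sample_params(family, rng))

    if tuner == "mbo":
        from sklearn.ensemble import RandomForestRegressor

        while len(evaluated) < budget:
            Xobs = np.array([_encode_params(family, p) for p, _ in evaluated])
            yobs = np.array([l for _, l in evaluated])
            forest = RandomForestRegressor(n_estimators=50, random_state=seed).fit(Xobs, yobs)
            cands = [_sample_params(family, rng) for _ in range(64)]
            enc = np.array([_encode_params(family, c) for c in cands])
            tree_preds = np.stack([t.predict(enc) for t in forest.estimators_])
            lcb = tree_preds.mean(axis=0) - tree_preds.std(axis=0)
            score(cands[int(np.argmin(lcb))])

    best_params, _ = min(evaluated, key=lambda pl: pl[1])
    return ClassifierSpec(family=family, params=best_params, feature_set=table.feature_set)


# ---------------------------------------------------------------------------
# stacking


@dataclass
class EnsembleSpec:
    """A stacked ensemble: base (classifier, feature set) configurations plus
    an L2-penalized multinomial super-learner."""

    bases: list[tuple[ClassifierSpec, str]]  # (spec, feature-set tag)

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("an ensemble needs at least one base model")


def stack(
    spec: EnsembleSpec,
    train_tables: dict[str, FeatureTable] | FeatureTable,
    test_tables: dict[str, FeatureTable] | FeatureTable,
    label: str,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-fold stacking with a ridge multinomial super-learner.

    Base models produce out-of-fold class probabilities over the training
    rows; the super-learner (L2-penalized multinomial regression, penalty
    strength by internal cross-validation) is trained on those. At test time
    each base is refit on the full training set and its test probabilities
    are fed to the super-learner.
    """
    from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
    from sklearn.model_selection import StratifiedKFold

    if isinstance(train_tables, FeatureTable):
        train_tables = {tag: train_tables for _, tag in spec.bases}
    if isinstance(test_tables, FeatureTable):
        test_tables = {tag: test_tables for _, tag in spec.bases}

    any_train = next(iter(train_tables.values()))
    any_test = next(iter(test_tables.values()))
    y = np.asarray(any_train.y(label))
    classes = np.unique(y)
    ids = any_train.data.index.to_numpy()

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(ids, y))

    oof_blocks, test_blocks = [], []
    for b, (base, tag) in enumerate(spec.bases):
        tr_tab, te_tab = train_tables[tag], test_tables[tag]
        oof = np.zeros((len(ids), len(classes)))
        for f, (tr, va) in enumerate(folds):
            try:
                probs = fit_predict(
                    base, tr_tab.select_rows(ids[tr]), tr_tab.select_rows(ids[va]),
                    label, seed=seed + f,
                )
            except Exception as err:
                raise RuntimeError(
                    f"base model {base.family}/{tag} failed during stacking: {err}"
                ) from err
            for j, c in enumerate(probs.columns):
                oof[va, list(classes).index(c)] = probs.to_numpy()[:, j]
        oof_blocks.append(oof)
        probs = fit_predict(base, tr_tab, te_tab, label, seed=seed + 100 + b)
        block = np.zeros((len(te_tab), len(classes)))
        for j, c in enumerate(probs.columns):
            block[:, list(classes).index(c)] = probs.to_numpy()[:, j]
        test_blocks.append(block)

    Z_train = np.hstack(oof_blocks)
    Z_test = np.hstack(test_blocks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            meta = LogisticRegressionCV(
                Cs=np.logspace(-2, 2, 5), cv=3, max_iter=2000,
                scoring="neg_log_loss", random_state=seed,
            ).fit(Z_train, y)
        except ValueError:  # classes too small for internal CV
            meta = LogisticRegression(C=1.0, max_iter=2000).fit(Z_train, y)
    probs = meta.predict_proba(Z_test)
    out = np.zeros((len(any_test), len(classes)))
    for j, c in enumerate(meta.classes_):
        out[:, list(classes).index(c)] = probs[:, j]
    return pd.DataFrame(out, index=any_test.data.index, columns=list(classes))
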