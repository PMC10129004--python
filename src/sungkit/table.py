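"""Feature tables: calls x named numeric features, plus label columns.

The in-memory container is a thin wrapper around a pandas DataFrame indexed
by call_id. Label columns (individual_id, call_type, sequence_id) travel
with the features; every other column is a numeric feature. Each table
carries a ``feature_set`` tag (bioacoustic, dct, mfcc, or union).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "LABEL_COLUMNS",
    "impute_missing",
    "standardize",
    "read_feature_table",
]

LABEL_COLUMNS = ("individual_id", "call_type", "sequence_id")

#: f0/energy descriptors eligible for tree-ensemble imputation; other columns
#: are expected to be complete (measurement failures only happen on the f0
#: trace, not on duration or harmonicity, which are defined for every call).
F0_IMPUTABLE = (
    "q1f", "q2f", "q3f", "f.max", "q1t", "q2t", "q3t", "t.max",
    "f0.sta", "f0.mid", "f0.end", "f0.av", "f0.max", "tf0.max",
    "f0.slope.asc", "f0.slope.desc", "f0.slope.1st.half", "f0.slope.2nd.half",
    "f0.onset", "f0.offset",
)


class FeatureTable:
    """Calls x features with label columns and a feature-set tag."""

    def __init__(self, data: pd.DataFrame, feature_set: str = "union"):
        if data.index.has_duplicates:
            raise ValueError("duplicate call ids in feature table")
        self.data = data.copy()
        self.data.index.name = "call_id"
        self.feature_set = feature_set
        for col in self.feature_names:
            if not np.issubdtype(self.data[col].dtype, np.number):
                raise ValueError(f"feature column {col!r} is not numeric")

    # -- views -------------------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in LABEL_COLUMNS]

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def labels(self) -> pd.DataFrame:
        return self.data[[c for c in LABEL_COLUMNS if c in self.data.columns]]

    def y(self, label: str) -> np.ndarray:
        return self.data[label].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    # -- manipulation ------------------------------------------------------
    def select_rows(self, call_ids: Iterable[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(call_ids)], self.feature_set)

    def select_features(self, names: Sequence[str], feature_set: str | None = None) -> "FeatureTable":
        keep = list(names) + [c for c in LABEL_COLUMNS if c in self.data.columns]
        return FeatureTable(self.data[keep], feature_set or self.feature_set)

    def with_features(self, features: pd.DataFrame) -> "FeatureTable":
        out = self.data.copy()
        out[features.columns] = features
        return FeatureTable(out, self.feature_set)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data, self.feature_set)

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV with the feature-set tag in a JSON sidecar."""
        path = Path(path)
        self.data.to_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"feature_set": self.feature_set}))

    def __repr__(self) -> str:
        return (
            f"FeatureTable({len(self)} calls x {len(self.feature_names)} features, "
            f"set={self.feature_set!r})"
        )


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    sidecar = path.with_suffix(path.suffix + ".json")
    feature_set = "union"
    if sidecar.exists():
        feature_set = json.loads(sidecar.read_text()).get("feature_set", "union")
    return FeatureTable(df, feature_set)


def impute_missing(
    table: FeatureTable,
    columns: Sequence[str] | None = None,
    seed: int = 0,
    n_estimators: int = 100,
) -> FeatureTable:
    """Fill missing feature cells with iterative random-forest predictions.

    Each column with missing entries is regressed on the co-observed feature
    columns; imputation iterates until convergence (sklearn IterativeImputer
    with a RandomForestRegressor estimator). Observed cells are untouched.

    Parameters
    ----------
    columns
        Columns allowed to contain (and receive) imputed values. ``None``
        allows every feature column; the corpus pipeline passes
        :data:`F0_IMPUTABLE` since only f0-trace descriptors can fail to be
        measured.
    """
    feats = table.features
    eligible = list(feats.columns) if columns is None else [c for c in columns if c in feats.columns]
    fully_missing = [c for c in feats.columns if feats[c].isna().all()]
    if fully_missing:
        raise ValueError(f"column(s) entirely missing, cannot impute: {fully_missing}")
    bad = feats.drop(columns=eligible).isna()
    if bad.to_numpy().any():
        offenders = sorted(bad.columns[bad.any()])
        raise ValueError(f"missing values outside imputable columns: {offenders}")
    if not feats.isna().to_numpy().any():
        return table.copy()

    from sklearn.ensemble import RandomForestRegressor
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    imputer = IterativeImputer(
        estimator=RandomForestRegressor(n_estimators=n_estimators, random_state=seed),
        random_state=seed,
        max_iter=10,
        sample_posterior=False,
    )
    filled = imputer.fit_transform(feats.to_numpy(dtype=float))
    out = feats.copy()
    mask = feats.isna().to_numpy()
    vals = out.to_numpy(dtype=float)
    vals[mask] = filled[mask]
    out.iloc[:, :] = vals
    return table.with_features(out)


def standardize(table: FeatureTable, reference: FeatureTable | None = None) -> FeatureTable:
    """z-score each feature column using the reference table's mean and sd.

    The reference defaults to the table itself; in train/test evaluation the
    training partition supplies the statistics so no test information leaks
    into the transform. Zero-variance reference columns map to 0 with a
    warning.
    """
    if reference is None:
        reference = table
    if len(reference) < 2:
        raise ValueError("reference must have more than one row")
    if list(reference.feature_names) != list(table.feature_names):
        raise ValueError("reference feature columns do not match table")
    mu = reference.features.mean(axis=0)
    sd = reference.features.std(axis=0, ddof=1)
    zero = sd <= 0
    if zero.any():
        warnings.warn(
            f"zero-variance column(s) set to 0: {sorted(sd.index[zero])}", stacklevel=2
        )
    safe_sd = sd.where(~zero, 1.0)
    z = (table.features - mu) / safe_sd
    z.loc[:, zero[zero].index] = 0.0
    return table.with_features(z)
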