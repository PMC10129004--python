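"""Supervised UMAP projection and the iterated silhouette-profile diagnostic.

A supervised 2-D UMAP embedding (labels passed as the supervision target)
gives a quick visual and quantitative read on how separable call types or
individual signatures are in a feature space. Because the projection is
stochastic, cluster quality is profiled over repeated embeddings: each
repetition embeds with a fresh derived seed and scores every call's
silhouette in the 2-D space; scores are then averaged per call, per class
and overall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import FeatureTable

__all__ = ["Embedding", "SilhouetteProfile", "supervised_embed", "silhouette_profile"]


@dataclass
class Embedding:
    """2-D coordinates per call plus the hyperparameters that produced them."""

    coords: pd.DataFrame  # call_id-indexed, columns x, y
    params: dict = field(default_factory=dict)


@dataclass
class SilhouetteProfile:
    per_call: pd.Series        # mean silhouette per call over repetitions
    per_class_mean: pd.Series  # average silhouette width per class
    per_class_sd: pd.Series
    overall_mean: float
    n_reps: int
    label: str


def supervised_embed(
    table: FeatureTable,
    labels: str,
    n_neighbors: int = 100,
    min_dist: float = 0.01,
    seed: int = 0,
) -> Embedding:
    """Project the feature table to 2-D with label-supervised UMAP.

    Euclidean distances drive the neighbor graph; the label column is passed
    as the categorical supervision target. Deterministic for a given seed.
    ``n_neighbors`` is clipped (with a warning) when the table is smaller
    than the default neighborhood.
    """
    import umap  # deferred: numba compilation is slow at import time

    X = table.X
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite values")
    if n_neighbors >= len(table):
        clipped = max(2, len(table) - 1)
        warnings.warn(
            f"n_neighbors={n_neighbors} >= n rows {len(table)}; clipped to {clipped}",
            stacklevel=2,
        )
        n_neighbors = clipped
    y = pd.Categorical(table.y(labels)).codes
    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        n_components=2,
        metric="euclidean",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced determinism
        coords = reducer.fit_transform(X, y=y)
    df = pd.DataFrame(coords, index=table.data.index, columns=["x", "y"])
    return Embedding(
        df,
        params={
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "metric": "euclidean",
            "supervision": labels,
            "seed": seed,
            "target_weight": "library default",
        },
    )


def silhouette_profile(
    table: FeatureTable,
    labels: str,
    n_reps: int = 100,
    seed: int = 0,
    n_neighbors: int = 100,
    min_dist: float = 0.01,
) -> SilhouetteProfile:
    """Silhouette statistics over repeated supervised embeddings.

    For each repetition the table is embedded with seed ``seed + rep`` and
    Euclidean silhouette scores are computed in the 2-D space. Classes with
    a single member are excluded (silhouette is undefined for them) with a
    warning. The overall mean is the size-weighted mean of per-class means.
    """
    from sklearn.metrics import silhouette_samples

    y = pd.Series(table.y(labels), index=table.data.index)
    counts = y.value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        warnings.warn(f"excluding single-member class(es): {singletons}", stacklevel=2)
        table = table.select_rows(y.index[~y.isin(singletons)])
        y = y[~y.isin(singletons)]
    if y.nunique() < 2:
        raise ValueError("silhouette requires at least two classes with >= 2 members")

    scores = np.empty((n_reps, len(table)))
    for rep in range(n_reps):
        emb = supervised_embed(
            table, labels, n_neighbors=n_neighbors, min_dist=min_dist, seed=seed + rep
        )
        scores[rep] = silhouette_samples(emb.coords.to_numpy(), y.to_numpy())
    per_call = pd.Series(scores.mean(axis=0), index=table.data.index, name="silhouette")
    per_class_mean = per_call.groupby(y).mean()
    per_class_sd = per_call.groupby(y).std(ddof=1)
    overall = float(per_call.mean())
    return SilhouetteProfile(
        per_call=per_call,
        per_class_mean=per_class_mean,
        per_class_sd=per_class_sd,
        overall_mean=overall,
        n_reps=n_reps,
        label=labels,
    )
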