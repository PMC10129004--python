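"""Shared fixtures: small seeded synthetic corpora and feature tables."""

import numpy as np
import pandas as pd
import pytest

import sungkit as sk
from sungkit.table import FeatureTable


@pytest.fixture(scope="session")
def small_corpus():
    """~200 calls, 10 individuals x 5 types, with waveforms."""
    cfg = sk.SyntheticConfig(n_calls=200, seed=11, waveforms=True)
    corpus, gt = sk.generate_corpus(cfg)
    return corpus, gt


@pytest.fixture(scope="session")
def dct_table(small_corpus):
    corpus, _ = small_corpus
    return sk.build_feature_table(corpus, "dct")


@pytest.fixture(scope="session")
def dct_table_z(dct_table):
    return sk.standardize(dct_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_call(call_id="c0", times=None, f0=None, duration=None, hnr=10.0, **kw):
    """Convenience constructor for a single synthetic call."""
    if times is None:
        times = np.linspace(0.0, 0.2, 50)
    if f0 is None:
        f0 = np.full_like(times, 500.0)
    return sk.Call(
        call_id=call_id,
        individual_id=kw.pop("individual_id", "ind1"),
        call_type=kw.pop("call_type", "P"),
        sequence_id=kw.pop("sequence_id", "s1"),
        f0_contour=np.column_stack([times, f0]),
        duration=duration if duration is not None else float(times[-1]),
        hnr=hnr,
        **kw,
    )


def make_table(X, labels, feature_set="dct", label_col="call_type", index=None):
    """Wrap a feature matrix + one label vector into a FeatureTable."""
    X = np.asarray(X, dtype=float)
    idx = index if index is not None else [f"c{i}" for i in range(len(X))]
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])], index=idx)
    df[label_col] = list(labels)
    for col in ("individual_id", "call_type", "sequence_id"):
        if col not in df.columns:
            df[col] = [f"u{i}" for i in range(len(X))] if col == "sequence_id" else "x"
    return FeatureTable(df, feature_set)
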