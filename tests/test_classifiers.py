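"""Classifier families: VIF reduction, balanced DFA, PCA front-end, tuning,
class weighting, and stacking."""

import numpy as np
import pandas as pd
import pytest

import sungkit as sk
from sungkit.classifiers import (
    ClassifierSpec,
    EnsembleSpec,
    HYPERPARAMETER_SPACES,
    balanced_subsample_size,
    default_spec,
    fit_predict,
    pca_frontend_select,
    stack,
    stepwise_vif_reduce,
    tune,
)
from sungkit.table import FeatureTable

from conftest import make_table


def oracle_vif(X, j):
    """Direct-regression VIF for column j."""
    others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
    coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
    resid = X[:, j] - others @ coef
    r2 = 1 - resid @ resid / ((X[:, j] - X[:, j].mean()) ** 2).sum()
    return np.inf if r2 >= 1 - 1e-12 else 1 / (1 - r2)


class TestVif:
    def test_independent_features_all_kept(self, rng):
        tab = make_table(rng.normal(size=(200, 5)), ["a"] * 200)
        assert stepwise_vif_reduce(tab) == tab.feature_names

    def test_duplicate_drops_exactly_one(self, rng):
        X = rng.normal(size=(100, 3))
        X = np.column_stack([X, X[:, 0]])
        tab = make_table(X, ["a"] * 100)
        kept = stepwise_vif_reduce(tab)
        assert len(kept) == 3
        assert "f0" in kept and "f3" not in kept  # later-listed duplicate dropped

    def test_correlated_block_reduced_below_threshold(self, rng):
        # 5 features with rho = 0.95 common factor
        z = rng.normal(size=(300, 1))
        X = np.sqrt(0.95) * z + np.sqrt(0.05) * rng.normal(size=(300, 5))
        tab = make_table(X, ["a"] * 300)
        kept = stepwise_vif_reduce(tab, threshold=5.0)
        idx = [tab.feature_names.index(k) for k in kept]
        Xk = X[:, idx]
        for j in range(Xk.shape[1]):
            assert oracle_vif(Xk, j) < 5.0


class TestDfa:
    def test_balanced_training_counts(self, rng):
        X = np.vstack([rng.normal(i * 4, 1, (30 + 10 * i, 3)) for i in range(3)])
        labels = ["a"] * 30 + ["b"] * 40 + ["c"] * 50
        tab = make_table(X, labels)
        # balanced_n larger than the smallest class is rejected
        with pytest.raises(ValueError, match="smallest class"):
            sk.dfa_fit_predict(tab, tab, "call_type", balanced_n=31)
        probs = sk.dfa_fit_predict(tab, tab, "call_type", balanced_n=20, seed=0)
        assert probs.shape == (120, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_separated_classes_high_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 1, (60, 3)), rng.normal(8, 1, (60, 3))])
        tab = make_table(X, ["a"] * 60 + ["b"] * 60)
        test = make_table(
            np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(8, 1, (20, 3))]),
            ["a"] * 20 + ["b"] * 20,
        )
        probs = sk.dfa_fit_predict(tab, test, "call_type", seed=1)
        pred = probs.idxmax(axis=1)
        assert (pred.to_numpy() == test.y("call_type")).mean() > 0.95

    def test_balanced_subsample_arithmetic(self):
        assert balanced_subsample_size(206) == 137
        assert balanced_subsample_size(71) == 47

    def test_front_ends_run(self, rng):
        X = np.vstack([rng.normal(0, 1, (40, 6)), rng.normal(4, 1, (40, 6))])
        X = np.column_stack([X, X[:, 0]])  # collinear column for the VIF path
        tab = make_table(X, ["a"] * 40 + ["b"] * 40)
        p1 = sk.dfa_fit_predict(tab, tab, "call_type", vif_threshold=5.0, seed=0)
        p2 = sk.dfa_fit_predict(tab, tab, "call_type", n_pcs=3, seed=0)
        for p in (p1, p2):
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_mfcc_sd_block_dropped_for_dfa(self, rng, small_corpus):
        """DFA on the MFCC set uses only the 96 frame-mean columns; shuffling
        the sd block must not change its predictions."""
        corpus, _ = small_corpus
        from sungkit.features import build_feature_table
        from sungkit.table import FeatureTable, standardize

        table = standardize(build_feature_table(corpus.subset(corpus.call_ids[:120]), "mfcc"))
        spec = ClassifierSpec("dfa", params={"n_pcs": 5}, feature_set="mfcc")
        p1 = fit_predict(spec, table, table, "call_type", seed=0)
        scrambled = table.data.copy()
        sd_cols = [c for c in table.feature_names if c.endswith(".sd")]
        scrambled[sd_cols] = rng.permutation(scrambled[sd_cols].to_numpy())
        p2 = fit_predict(spec, FeatureTable(scrambled, "mfcc"), table, "call_type", seed=0)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-9)


class TestPcaFrontend:
    def test_one_informative_direction(self, rng):
        n = 150
        labels = np.array(["a"] * 75 + ["b"] * 75)
        signal = (labels == "a").astype(float) * 4
        X = rng.normal(size=(n, 50)) * 0.5
        X[:, 0] += signal
        tab = make_table(X, labels)
        k = pca_frontend_select(tab, "call_type", max_pcs=50, seed=0)
        assert 1 <= k <= 5

    def test_result_in_bounds(self, rng):
        tab = make_table(rng.normal(size=(60, 8)), ["a"] * 30 + ["b"] * 30)
        k = pca_frontend_select(tab, "call_type", max_pcs=8, seed=0)
        assert 1 <= k <= 8

    def test_max_pcs_validation(self, rng):
        tab = make_table(rng.normal(size=(30, 4)), ["a"] * 15 + ["b"] * 15)
        with pytest.raises(ValueError, match="max_pcs"):
            pca_frontend_select(tab, "call_type", max_pcs=1)

    def test_monotone_curve_selects_boundary(self, monkeypatch, rng):
        """If the raw CV-loss curve decreases monotonically, the smoothed
        argmin is the largest component count."""
        from statsmodels.nonparametric.smoothers_lowess import lowess

        ks = np.arange(1, 21).astype(float)
        losses = 1.0 / ks  # monotone decreasing
        smoothed = lowess(losses, ks, frac=1.0, return_sorted=False)
        assert int(ks[np.argmin(smoothed)]) == 20


class TestTune:
    @pytest.mark.parametrize("family", ["svm", "xgboost", "nn"])
    def test_tuned_params_inside_ranges(self, family, rng):
        X = np.vstack([rng.normal(0, 1, (25, 3)), rng.normal(5, 1, (25, 3))])
        tab = make_table(X, ["a"] * 25 + ["b"] * 25)
        spec = tune(tab, family, "call_type", budget=5, cv=(2, 1), seed=0, tuner="random")
        space = HYPERPARAMETER_SPACES[family]
        for name, rngspec in space.items():
            if name not in spec.params:
                continue
            v = spec.params[name]
            if isinstance(rngspec, list):
                assert v in rngspec
            else:
                assert rngspec[0] <= v <= rngspec[1]

    def test_deterministic(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(5, 1, (20, 3))])
        tab = make_table(X, ["a"] * 20 + ["b"] * 20)
        s1 = tune(tab, "svm", "call_type", budget=6, cv=(2, 1), seed=3)
        s2 = tune(tab, "svm", "call_type", budget=6, cv=(2, 1), seed=3)
        assert s1.params == s2.params

    def test_tuned_beats_arbitrary_default_on_toy(self, rng):
        X = np.vstack([rng.normal(0, 1, (40, 4)), rng.normal(3, 1, (40, 4))])
        tab = make_table(X, ["a"] * 40 + ["b"] * 40)
        from sungkit.classifiers import _cv_log_loss

        spec = tune(tab, "svm", "call_type", budget=8, cv=(3, 1), seed=1)
        tuned_loss = _cv_log_loss("svm", spec.params, tab, "call_type", 3, 1, 1)
        arbitrary = {"kernel": "polynomial", "degree": 4, "C": 2.0**-7, "gamma": 2.0**5}
        default_loss = _cv_log_loss("svm", arbitrary, tab, "call_type", 3, 1, 1)
        assert tuned_loss <= default_loss

    def test_small_budget_warns_and_uses_random_search(self, rng):
        X = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(5, 1, (15, 2))])
        tab = make_table(X, ["a"] * 15 + ["b"] * 15)
        with pytest.warns(UserWarning, match="random search"):
            tune(tab, "svm", "call_type", budget=3, cv=(2, 1), seed=0)

    def test_out_of_range_spec_rejected(self):
        with pytest.raises(ValueError, match="outside range"):
            ClassifierSpec("svm", params={"C": 2.0**9})


class TestFitPredict:
    @pytest.mark.parametrize("family", ["svm", "xgboost", "nn", "dfa"])
    def test_probability_rows_sum_to_one(self, family, rng):
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(4, 1, (30, 3))])
        tab = make_table(X, ["a"] * 30 + ["b"] * 30)
        spec = default_spec(family)
        probs = fit_predict(spec, tab, tab, "call_type", seed=0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_svm_deterministic(self, rng):
        X = np.vstack([rng.normal(0, 1, (25, 3)), rng.normal(4, 1, (25, 3))])
        tab = make_table(X, ["a"] * 25 + ["b"] * 25)
        p1 = fit_predict(default_spec("svm"), tab, tab, "call_type", seed=5)
        p2 = fit_predict(default_spec("svm"), tab, tab, "call_type", seed=5)
        np.testing.assert_array_equal(p1.to_numpy(), p2.to_numpy())

    def test_class_weights_help_minority_recall(self):
        """On a 9:1 imbalanced overlap problem, inverse-frequency weights give
        strictly higher minority recall than no weighting (averaged over
        20 seeds)."""
        deltas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(0, 1.5, (90, 2)), rng.normal(2.0, 1.5, (10, 2))])
            labels = ["maj"] * 90 + ["min"] * 10
            tab = make_table(X, labels)
            Xt = np.vstack([rng.normal(0, 1.5, (45, 2)), rng.normal(2.0, 1.5, (15, 2))])
            test = make_table(Xt, ["maj"] * 45 + ["min"] * 15)
            recalls = {}
            for mode in ("inverse", None):
                spec = ClassifierSpec("svm", params={"kernel": "radial", "C": 1.0, "gamma": 0.5},
                                      class_weighting=mode, probability=False)
                pred = fit_predict(spec, tab, test, "call_type", seed=seed).idxmax(axis=1)
                recalls[mode] = (pred.to_numpy()[45:] == "min").mean()
            deltas.append(recalls["inverse"] - recalls[None])
        assert np.mean(deltas) > 0

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier family"):
            ClassifierSpec("forest")


class TestStack:
    def _tables(self, rng, n_per=40):
        X = np.vstack([rng.normal(0, 1, (n_per, 4)), rng.normal(4, 1, (n_per, 4))])
        labels = ["a"] * n_per + ["b"] * n_per
        tab = make_table(X, labels)
        Xt = np.vstack([rng.normal(0, 1, (15, 4)), rng.normal(4, 1, (15, 4))])
        test = make_table(Xt, ["a"] * 15 + ["b"] * 15)
        return tab, test

    def test_rows_sum_to_one(self, rng):
        train, test = self._tables(rng)
        ens = EnsembleSpec([(default_spec("svm"), "dct"), (default_spec("xgboost"), "dct")])
        probs = stack(ens, train, test, "call_type", seed=0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_single_base_close_to_base_alone(self, rng):
        train, test = self._tables(rng)
        base = default_spec("svm")
        alone = fit_predict(base, train, test, "call_type", seed=0).idxmax(axis=1)
        stacked = stack(EnsembleSpec([(base, "dct")]), train, test, "call_type", seed=0).idxmax(axis=1)
        truth = test.y("call_type")
        bac_alone = np.mean([(alone[truth == c] == c).mean() for c in ("a", "b")])
        bac_stack = np.mean([(stacked[truth == c] == c).mean() for c in ("a", "b")])
        assert abs(bac_alone - bac_stack) <= 0.03 + 1e-9

    def test_oracle_plus_random_base_stays_strong(self, rng):
        train, test = self._tables(rng, n_per=50)
        good = default_spec("svm")  # separable data: effectively an oracle
        noisy = ClassifierSpec("nn", params={"epochs": 25, "n_layers": 1, "neurons1": 5,
                                             "dropout": 0.5, "input_dropout": 0.5})
        ens = EnsembleSpec([(good, "dct"), (noisy, "dct")])
        pred = stack(ens, train, test, "call_type", seed=0).idxmax(axis=1)
        truth = test.y("call_type")
        bac = np.mean([(pred[truth == c] == c).mean() for c in ("a", "b")])
        assert bac >= 0.95

    def test_failed_base_named(self, rng):
        train, test = self._tables(rng)
        bad = ClassifierSpec("dfa", params={"balanced_n": 10_000})
        ens = EnsembleSpec([(default_spec("svm"), "dct"), (bad, "dct")])
        with pytest.raises(RuntimeError, match="dfa"):
            stack(ens, train, test, "call_type", seed=0)

    def test_paper_configurations_constructible(self):
        """3 per-classifier stacks, 3 per-set stacks, and the 9-model stack
        are all expressible from configuration alone."""
        fams = ("svm", "nn", "xgboost")
        sets = ("bioacoustic", "dct", "mfcc")
        per_classifier = [
            EnsembleSpec([(default_spec(f, feature_set=s), s) for s in sets]) for f in fams
        ]
        per_set = [
            EnsembleSpec([(default_spec(f, feature_set=s), s) for f in fams]) for s in sets
        ]
        full = EnsembleSpec(
            [(default_spec(f, feature_set=s), s) for f in fams for s in sets]
        )
        assert len(per_classifier) == 3 and len(per_set) == 3
        assert len(full.bases) == 9
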