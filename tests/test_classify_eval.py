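"""AUROC, classifiers, band thresholds and the likelihood-ratio metric block."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hostpanel.classify_eval import (
    BandConfig,
    ClassifierSpec,
    MLPEnsembleClassifier,
    SVMRbfClassifier,
    auroc,
    band_fraction_from_likelihood_ratio,
    compute_band_metrics,
    evaluate_panel,
    fit_band_thresholds,
    mauroc,
)


def pair_counting_auroc(scores, labels):
    """O(n^2) oracle: concordant pairs + half ties over all pos/neg pairs."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels).astype(bool)]
    neg = scores[~np.asarray(labels).astype(bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_ordering(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_one_class_absent_is_an_error(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        # integer scores force ties
        scores = rng.integers(0, 8, size=n).astype(float)
        labels = np.zeros(n, dtype=int)
        labels[rng.permutation(n)[: int(rng.integers(1, n))] ] = 1
        if labels.sum() in (0, n):
            return
        assert auroc(scores, labels) == pytest.approx(
            pair_counting_auroc(scores, labels), abs=1e-12
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


def three_blob_data(n=60, seed=0, sep=6.0):
    rng = np.random.default_rng(seed)
    classes = np.repeat(["bacterial", "viral", "noninfected"], n)
    centers = {"bacterial": (0, 0), "viral": (sep, 0), "noninfected": (0, sep)}
    X = np.vstack([rng.normal(centers[c], 1.0, size=(1, 2)) for c in classes])
    cols = ["f1", "f2"]
    return pd.DataFrame(X, columns=cols), classes


class TestClassifiers:
    def test_separable_data_near_perfect_training_auroc(self):
        X, y = three_blob_data(seed=2)
        model = MLPEnsembleClassifier(ensemble_size=2, seed=0).fit(X, y)
        proba = model.predict_proba(X)
        for i, cls in enumerate(model.classes_):
            assert auroc(proba[:, i], y == cls) >= 0.99

    def test_same_seed_identical_probabilities(self):
        X, y = three_blob_data(seed=3)
        p1 = MLPEnsembleClassifier(ensemble_size=3, seed=5).fit(X, y).predict_proba(X)
        p2 = MLPEnsembleClassifier(ensemble_size=3, seed=5).fit(X, y).predict_proba(X)
        np.testing.assert_allclose(p1, p2, atol=1e-12, rtol=0)

    def test_ensemble_of_one_matches_single_member(self):
        from sklearn.neural_network import MLPClassifier

        X, y = three_blob_data(seed=4)
        ens = MLPEnsembleClassifier(ensemble_size=1, seed=7).fit(X, y)
        subseed = int(np.random.default_rng(7).integers(0, 2**31 - 1, size=1)[0])
        single = MLPClassifier(
            hidden_layer_sizes=(32,), alpha=1e-3, learning_rate_init=1e-3,
            max_iter=300, random_state=subseed,
        ).fit(X.to_numpy(), y)
        np.testing.assert_allclose(
            ens.predict_proba(X), single.predict_proba(X.to_numpy()), atol=1e-12
        )

    def test_triplets_sum_to_one(self):
        X, y = three_blob_data(seed=5)
        proba = MLPEnsembleClassifier(ensemble_size=2, seed=1).fit(X, y).predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert ((proba >= 0) & (proba <= 1)).all()

    def test_single_class_input_is_an_error(self):
        X = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError):
            MLPEnsembleClassifier().fit(X, ["viral", "viral"])

    def test_svm_baseline_same_interface(self):
        X, y = three_blob_data(n=30, seed=6)
        model = ClassifierSpec(family="svm_rbf", seed=0).build().fit(X, y)
        assert isinstance(model, SVMRbfClassifier)
        assert model.predict_proba(X).shape == (len(y), 3)


class TestBandThresholds:
    def scores_labels(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        labels = rng.random(n) < 0.4
        scores = np.where(
            labels, rng.beta(5, 2, size=n), rng.beta(2, 5, size=n)
        )
        return scores, labels

    def test_targets_met_on_training_scores(self):
        scores, labels = self.scores_labels()
        cfg = fit_band_thresholds(scores, labels, 98.0, 92.0)
        metrics = compute_band_metrics(scores, labels, cfg)
        assert metrics.band1_sensitivity >= 98.0
        assert metrics.band4_specificity >= 92.0

    def test_full_sensitivity_target_puts_t1_below_all_positives(self):
        scores, labels = self.scores_labels(seed=1)
        cfg = fit_band_thresholds(scores, labels, 100.0, 80.0)
        assert cfg.t1 <= scores[labels].min()

    def test_raising_sensitivity_target_never_raises_t1(self):
        scores, labels = self.scores_labels(seed=2)
        t1s = [
            fit_band_thresholds(scores, labels, target, 95.0).t1
            for target in (90.0, 95.0, 99.0, 100.0)
        ]
        assert all(a >= b for a, b in zip(t1s, t1s[1:]))

    def test_crossed_extremes_still_satisfy_both_targets(self):
        # cleanly separated scores: aggressive extremes cross and are pulled
        # to the middle, keeping both targets satisfied
        rng = np.random.default_rng(6)
        labels = rng.random(300) < 0.5
        scores = np.where(labels, rng.beta(8, 2, 300), rng.beta(2, 8, 300))
        cfg = fit_band_thresholds(scores, labels, 98.0, 92.0)
        m = compute_band_metrics(scores, labels, cfg)
        assert m.band1_sensitivity >= 98.0
        assert m.band4_specificity >= 92.0

    def test_degenerate_targets_advise_lowering(self):
        # the only positive sits at the bottom of the score range with
        # sensitivity target 100 and specificity target 0: both extremes pin
        # to the bottom sentinel and no rule-out/rule-in split exists
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([1, 0, 0, 0])
        with pytest.raises(ValueError, match="lower"):
            fit_band_thresholds(scores, labels, 100.0, 0.0)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="t1 < t2 < t3"):
            BandConfig(0.5, 0.4, 0.6)


class TestBandMetrics:
    def test_hand_counted_contingency(self):
        # 10 positives (1 in band 1), 10 negatives (5 in band 1)
        cfg = BandConfig(0.3, 0.5, 0.7)
        pos = np.array([0.1] + [0.6] * 9)
        neg = np.array([0.1] * 5 + [0.6] * 5)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 10 + [0] * 10)
        m = compute_band_metrics(scores, labels, cfg)
        assert m.band1_sensitivity == pytest.approx(90.0)
        assert m.lr_minus == pytest.approx((1 / 10) / (5 / 10))
        assert m.fraction1 == pytest.approx(100 * 6 / 20)

    def test_perfect_test(self):
        cfg = BandConfig(0.3, 0.5, 0.7)
        scores = np.array([0.9] * 5 + [0.1] * 5)
        labels = np.array([1] * 5 + [0] * 5)
        m = compute_band_metrics(scores, labels, cfg)
        assert m.lr_minus == 0.0
        assert m.band4_specificity == 100.0
        assert np.isinf(m.lr_plus)

    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(3)
        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        cfg = BandConfig(0.25, 0.5, 0.75)
        m = compute_band_metrics(scores, labels, cfg)
        bands = cfg.bands(scores)
        fractions = [100 * (bands == b).mean() for b in (1, 2, 3, 4)]
        assert sum(fractions) == pytest.approx(100.0, abs=1e-9)
        assert m.fraction1 == pytest.approx(fractions[0])
        assert m.fraction4 == pytest.approx(fractions[3])

    def test_prevalence_identity_exact_on_finite_data(self):
        rng = np.random.default_rng(4)
        n = 400
        labels = rng.random(n) < 0.3
        scores = np.where(labels, rng.beta(4, 2, n), rng.beta(2, 4, n))
        cfg = BandConfig(0.2, 0.5, 0.8)
        m = compute_band_metrics(scores, labels, cfg)
        pi = labels.mean()
        frac4 = band_fraction_from_likelihood_ratio(
            pi, m.lr_plus, 1 - m.band4_specificity / 100
        )
        assert frac4 == pytest.approx(m.fraction4, abs=1e-9)

    def test_lr_ordering_on_separable_scores(self):
        rng = np.random.default_rng(5)
        labels = rng.random(400) < 0.5
        scores = np.where(labels, rng.beta(6, 2, 400), rng.beta(2, 6, 400))
        cfg = fit_band_thresholds(scores, labels, 95.0, 90.0)
        m = compute_band_metrics(scores, labels, cfg)
        assert m.lr_minus <= 1 <= m.lr_plus


def test_evaluate_panel_end_to_end(split_study):
    X_train, y_train, _, X_val, y_val = split_study
    panel = [c for c in X_train.columns if not c.startswith(("HKG", "NOISE"))][:6]
    result = evaluate_panel(
        panel, X_train, y_train, X_val, y_val,
        ClassifierSpec(family="mlp_ensemble", ensemble_size=2, seed=0),
        band1_sensitivity_target=90.0, band4_specificity_target=85.0,
        cv_folds=3,
    )
    metrics = result["metrics"]
    assert set(metrics.columns.get_level_values("dataset")) == {"train", "validation"}
    assert metrics.loc["auroc"].min() > 0.5
    for cls, cfg in result["thresholds"].items():
        assert cfg.t1 < cfg.t2 < cfg.t3


def test_mauroc_is_mean_of_one_vs_rest(split_study):
    X_train, y_train, _, _, _ = split_study
    rng = np.random.default_rng(0)
    proba = rng.dirichlet([1, 1, 1], size=len(y_train))
    classes = ["bacterial", "noninfected", "viral"]
    expected = np.mean([auroc(proba[:, i], y_train == c) for i, c in enumerate(classes)])
    assert mauroc(proba, y_train, classes) == pytest.approx(expected)
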