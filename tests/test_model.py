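"""Tests for the linear-SVM signature: training, calibration, the published
coefficients, confusion metrics and ROC/AUC with confidence intervals."""

import numpy as np
import pytest

from adcradiomics.augment import SplitSet
from adcradiomics.model import (
    PUBLISHED_COEFFS,
    PUBLISHED_INTERCEPT,
    SignatureModel,
    SVMConfig,
    confusion_metrics,
    evaluate_published_signature,
    radiomic_score,
    roc_with_ci,
    train_signature,
)


class TestPublishedSignature:
    def test_zero_vector_returns_intercept(self):
        row = {"cv-m": 0.0, "mu-u": 0.0, "s-s": 0.0, "sigma-IQR": 0.0}
        assert evaluate_published_signature(row) == pytest.approx(-0.04)

    def test_unit_vector_arithmetic(self):
        row = {"cv-m": 1.0, "mu-u": 1.0, "s-s": 1.0, "sigma-IQR": 1.0}
        assert evaluate_published_signature(row) == pytest.approx(1.69)

    def test_sigma_iqr_strictly_decreases_g(self, rng):
        base = {"cv-m": 0.4, "mu-u": 0.6, "s-s": 0.5, "sigma-IQR": 0.0}
        values = [evaluate_published_signature({**base, "sigma-IQR": v})
                  for v in np.linspace(0, 1, 11)]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_unicode_aliases_accepted(self):
        row = {"cv−m": 0.0, "μ−u": 0.0, "s−s": 0.0, "σ−IQR": 0.0}
        assert evaluate_published_signature(row) == pytest.approx(-0.04)

    def test_missing_symbol_is_named(self):
        with pytest.raises(KeyError, match="sigma-IQR"):
            evaluate_published_signature({"cv-m": 0, "mu-u": 0, "s-s": 0})

    def test_weights_mirror_printed_coefficients(self):
        assert PUBLISHED_INTERCEPT == -0.04
        assert PUBLISHED_COEFFS["cv-m"] == 1.67
        assert PUBLISHED_COEFFS["sigma-IQR"] == -1.12


class TestRadiomicScore:
    def _model(self, calibration=(1.0, 0.0)):
        return SignatureModel(
            ("a", "b", "c", "d"), np.array([1.0, 1.0, 1.0, 1.0]), 0.0, calibration
        )

    def test_zero_decision_gives_half(self):
        model = self._model()
        assert radiomic_score(model, {"a": 0, "b": 0, "c": 0, "d": 0}) == pytest.approx(0.5)

    def test_monotone_in_decision_value(self, rng):
        model = self._model(calibration=(2.5, -0.3))
        rows = rng.normal(0, 1, (50, 4))
        d = model.decision_value(rows)
        s = model.score(rows)
        order = np.argsort(d)
        assert np.all(np.diff(s[order]) >= 0)

    def test_missing_feature_is_named(self):
        model = self._model()
        with pytest.raises(KeyError, match="'d'"):
            radiomic_score(model, {"a": 0, "b": 0, "c": 0})

    def test_json_round_trip(self, tmp_path):
        model = self._model(calibration=(1.7, 0.2))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SignatureModel.from_json(path)
        assert back.feature_names == model.feature_names
        np.testing.assert_allclose(back.weights, model.weights)
        assert back.calibration == model.calibration


def _separable_split(rng, n=60, gap=2.0, noise=0.0):
    X = np.vstack([rng.normal(0, 0.3, (n // 2, 4)), rng.normal(gap, 0.3, (n // 2, 4))])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    if noise:
        X += rng.normal(0, noise, X.shape)
    order = rng.permutation(n)
    return SplitSet(X[order], y[order], X[:10], y[:10], "random", 0)


class TestTrainSignature:
    CFG = SVMConfig(cv_runs=3, bayes_opt_iters=8, seed=42)

    def test_separable_data_trains_perfectly(self, rng):
        split = _separable_split(rng)
        model = train_signature(split, self.CFG)
        cv = model.provenance["cv"]
        assert cv["training_auc"] == pytest.approx(1.0)
        assert cv["training_informedness"] == pytest.approx(1.0)

    def test_score_reproduces_waterfall_ordering(self, rng):
        split = _separable_split(rng, noise=0.5)
        model = train_signature(split, self.CFG)
        d = model.decision_value(split.train_X)
        s = model.score(split.train_X)
        np.testing.assert_array_equal(np.argsort(d), np.argsort(s))

    def test_recovers_planted_linear_rule(self):
        # labels from a known linear rule + noise: the recovered weight
        # vector should align with the true one (cosine >= 0.9 at n = 150)
        cosines = []
        for rep in range(3):
            r = np.random.default_rng(100 + rep)
            true_w = np.array([1.5, 1.0, 0.5, -1.2])
            X = r.normal(0.5, 0.25, (150, 4))
            logits = (X - 0.5) @ true_w + r.normal(0, 0.3, 150)
            y = (logits > 0).astype(int)
            if len(np.unique(y)) < 2:
                continue
            split = SplitSet(X, y, X[:10], y[:10], "random", rep)
            model = train_signature(split, SVMConfig(cv_runs=3, bayes_opt_iters=8, seed=rep))
            w = model.weights
            cosines.append(w @ true_w / np.linalg.norm(w) / np.linalg.norm(true_w))
        assert np.median(cosines) >= 0.9

    def test_provenance_records_search_settings(self, rng):
        split = _separable_split(rng, noise=0.4)
        model = train_signature(split, self.CFG, feature_names=["p", "q", "r", "s"])
        assert model.feature_names == ("p", "q", "r", "s")
        assert model.provenance["config"]["cv_runs"] == 3
        assert model.provenance["C"] > 0 and model.provenance["gamma"] > 0


class TestConfusionMetrics:
    def test_printed_training_errors_reproduce_reported_metrics(self):
        # 75 P / 75 N with 11 FN and 10 FP
        y = np.array([1] * 75 + [0] * 75)
        pred = np.array([1] * 64 + [0] * 11 + [1] * 10 + [0] * 65)
        rep = confusion_metrics(y, pred)
        out = rep.report()
        assert (out["SN"], out["SP"], out["I"]) == (85, 87, 0.72)

    def test_printed_test_errors_reproduce_reported_metrics(self):
        # 25 P / 25 N with 4 FN and 4 FP
        y = np.array([1] * 25 + [0] * 25)
        pred = np.array([1] * 21 + [0] * 4 + [1] * 4 + [0] * 21)
        out = confusion_metrics(y, pred).report()
        assert out["SN"] == out["SP"] == 84
        assert out["I"] == 0.68
        assert out["PPV"] == out["NPV"] == 84

    def test_perfect_classifier(self):
        y = np.array([0, 0, 1, 1])
        rep = confusion_metrics(y, y, scores=y.astype(float), n_boot=50)
        out = rep.report()
        assert out["SN"] == out["SP"] == out["PPV"] == out["NPV"] == 100
        assert out["I"] == 1.0 and out["AUC"] == 1.0

    def test_informedness_identity_holds(self, rng):
        y = rng.integers(0, 2, 80)
        pred = rng.integers(0, 2, 80)
        rep = confusion_metrics(y, pred)
        if rep.informedness is not None:
            assert rep.informedness == pytest.approx(
                rep.sensitivity + rep.specificity - 1.0
            )
        assert rep.n == 80

    def test_single_class_reports_not_applicable(self):
        y = np.ones(10, dtype=int)
        rep = confusion_metrics(y, np.ones(10, dtype=int))
        assert rep.report()["SP"] == "n/a"
        assert rep.report()["I"] == "n/a"


class TestRocWithCI:
    def test_scores_equal_labels_auc_one(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        *_, auc, ci = roc_with_ci(y.astype(float), y, n_boot=100)
        assert auc == 1.0

    def test_auc_equals_mann_whitney_u_statistic(self, rng):
        y = rng.integers(0, 2, 60)
        s = rng.normal(0, 1, 60) + 0.4 * y
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(s[y == 1], s[y == 0]).statistic
        *_, auc, _ = roc_with_ci(s, y, n_boot=50)
        assert auc == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))

    def test_reversing_scores_mirrors_auc(self, rng):
        y = rng.integers(0, 2, 50)
        s = rng.normal(0, 1, 50) + y
        *_, auc, _ = roc_with_ci(s, y, n_boot=50)
        *_, auc_rev, _ = roc_with_ci(-s, y, n_boot=50)
        assert auc_rev == pytest.approx(1.0 - auc)

    def test_bootstrap_ci_brackets_auc(self, rng):
        y = np.array([0, 1] * 40)
        s = rng.normal(0, 1, 80) + 0.8 * y
        *_, auc, (lo, hi) = roc_with_ci(s, y, n_boot=500, seed=3)
        assert lo <= auc <= hi
        assert 0 <= lo < hi <= 1

    def test_delong_ci_close_to_bootstrap(self, rng):
        y = np.array([0, 1] * 50)
        s = rng.normal(0, 1, 100) + 0.7 * y
        *_, auc_b, ci_b = roc_with_ci(s, y, method="bootstrap", n_boot=2000, seed=1)
        *_, auc_d, ci_d = roc_with_ci(s, y, method="delong")
        assert auc_b == auc_d
        assert ci_d[0] == pytest.approx(ci_b[0], abs=0.05)
        assert ci_d[1] == pytest.approx(ci_b[1], abs=0.05)
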