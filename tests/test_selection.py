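"""Tests for min-max normalization, LASSO screening, the exhaustive
4-feature SVM search and Holm-Bonferroni correction."""

import numpy as np
import pandas as pd
import pytest

from adcradiomics.selection import (
    NoSignificantComboError,
    exhaustive_quadruple_search,
    holm_bonferroni,
    informedness_from_counts,
    lasso_screen,
    minmax_normalize,
)


def _planted_table(rng, n=120, n_noise=130, informative=2, effect=2.0):
    """Binary-labelled, min-max-scaled table with a few shifted features
    among pure noise (the screen always runs on normalized features)."""
    y = np.array([0, 1] * (n // 2))
    cols = {}
    for i in range(informative):
        cols[f"sig{i}"] = rng.normal(0, 1, n) + effect * y
    for i in range(n_noise):
        cols[f"noise{i:03d}"] = rng.normal(0, 1, n)
    df = pd.DataFrame(cols)
    return (df - df.min()) / (df.max() - df.min()), y


class TestMinMaxNormalize:
    def test_maps_to_unit_interval(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        out, params = minmax_normalize(df)
        assert out["a"].tolist() == [0.0, 0.5, 1.0]

    def test_already_unit_feature_unchanged(self):
        df = pd.DataFrame({"a": [0.0, 0.25, 1.0]})
        out, _ = minmax_normalize(df)
        assert out["a"].tolist() == [0.0, 0.25, 1.0]

    def test_new_rows_can_exceed_one(self):
        df = pd.DataFrame({"a": [0.0, 10.0]})
        _, params = minmax_normalize(df)
        new = params.transform(pd.DataFrame({"a": [15.0]}))
        assert new["a"].iloc[0] == pytest.approx(1.5)  # not clipped

    def test_constant_feature_dropped_and_logged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        out, params = minmax_normalize(df)
        assert "flat" not in out.columns
        assert params.dropped == ["flat"]


class TestLassoScreen:
    def test_recovers_planted_signal_features(self, rng):
        hits = 0
        for rep in range(20):
            df, y = _planted_table(np.random.default_rng(1000 + rep))
            subset = lasso_screen(df, y, seed=rep, n_lambdas=25)
            if {"sig0", "sig1"} <= set(subset):
                hits += 1
        assert hits >= 19  # >= 95% inclusion

    def test_pure_noise_screen_is_usually_empty(self):
        # under the minimum-CV-error rule the null screen is empty in the
        # clear majority of datasets (the rule is liberal when it is not)
        sizes = []
        for rep in range(12):
            r = np.random.default_rng(5000 + rep)
            df, y = _planted_table(r, n=80, informative=0, n_noise=30)
            sizes.append(len(lasso_screen(df, y, seed=rep, n_lambdas=15)))
        assert sum(s == 0 for s in sizes) >= 6
        assert np.median(sizes) == 0

    def test_deterministic_under_seed(self, rng):
        df, y = _planted_table(rng)
        assert lasso_screen(df, y, seed=5, n_lambdas=25) == lasso_screen(df, y, seed=5, n_lambdas=25)

    def test_max_features_truncates_by_coefficient(self, rng):
        df, y = _planted_table(rng, effect=3.0)
        full = lasso_screen(df, y, seed=1, n_lambdas=25)
        capped = lasso_screen(df, y, seed=1, n_lambdas=25, max_features=4)
        assert capped == full[:4]


class TestHolmBonferroni:
    def test_hand_computed_step_down(self):
        assert holm_bonferroni([0.01, 0.04], alpha=0.05) == [True, True]
        assert holm_bonferroni([0.03, 0.04], alpha=0.05) == [False, False]

    def test_all_ones_rejected_nothing(self):
        assert holm_bonferroni([1.0, 1.0, 1.0], alpha=0.05) == [False] * 3

    def test_single_p_below_alpha(self):
        assert holm_bonferroni([0.025], alpha=0.05) == [True]

    def test_monotone_rejections(self, rng):
        p = rng.uniform(0, 1, 30)
        decisions = np.asarray(holm_bonferroni(p, alpha=0.2))
        if decisions.any():
            threshold = p[decisions].max()
            assert decisions[p <= threshold].all()

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 50) ** 2
        ours = holm_bonferroni(p, alpha=0.05)
        ref = multipletests(p, alpha=0.05, method="holm")[0]
        assert ours == ref.tolist()


class TestExhaustiveSearch:
    def test_combo_count_matches_binomial_coefficient(self, rng):
        df, y = _planted_table(rng, n=80, n_noise=15, informative=2, effect=2.5)
        sub = df[df.columns[:17]]
        result = exhaustive_quadruple_search(sub, y)
        assert len(result.combos) == 2380  # C(17, 4)

    def test_planted_signal_dominates_winner(self):
        # 4 informative features among 10: the winner is significant, at
        # least as informative as the planted quadruple itself, and built
        # mostly from the planted features
        for rep in range(5):
            r = np.random.default_rng(3000 + rep)
            y = np.array([0, 1] * 50)
            cols = {f"sig{i}": r.normal(0, 1, 100) + 1.5 * y for i in range(4)}
            cols.update({f"noise{i}": r.normal(0, 1, 100) for i in range(6)})
            df = pd.DataFrame(cols)
            result = exhaustive_quadruple_search(df, y)
            assert result.chosen.significant
            planted = next(
                c for c in result.combos
                if set(c.features) == {"sig0", "sig1", "sig2", "sig3"}
            )
            assert planted.significant
            assert result.chosen.informedness >= planted.informedness
            assert len(set(result.chosen_features) & set(planted.features)) >= 2

    def test_tie_break_smaller_p_then_names(self):
        from adcradiomics.selection import ComboResult, pick_winner

        a = ComboResult(("f1", "f2", "f3", "f4"), 1e-5, True, 0.8)
        b = ComboResult(("a1", "a2", "a3", "a4"), 1e-7, True, 0.8)
        c = ComboResult(("z1", "z2", "z3", "z4"), 1e-7, True, 0.8)
        assert pick_winner([a, b, c]) is b  # equal I: smaller p wins
        assert pick_winner([b, c]) is b  # equal I and p: lexicographic
        d = ComboResult(("m1", "m2", "m3", "m4"), 0.9e-3, True, 0.9)
        assert pick_winner([a, b, c, d]) is d  # highest informedness first

    def test_chosen_informedness_consistent_with_confusion_counts(self, rng):
        df, y = _planted_table(rng, n=60, n_noise=8, informative=2, effect=2.0)
        result = exhaustive_quadruple_search(df, y)
        c = result.chosen
        assert c.significant
        assert -1.0 <= c.informedness <= 1.0
        # recompute independently from a refit
        from sklearn.svm import SVC

        X = df[list(c.features)].to_numpy()
        d = SVC(kernel="linear", C=1.0).fit(X, y).decision_function(X)
        pred = (d > 0).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        assert c.informedness == pytest.approx(
            informedness_from_counts(tp, fn, tn, fp)
        )

    def test_no_significant_combo_raises_with_best_p(self, rng):
        y = np.array([0, 1] * 8)
        df = pd.DataFrame({f"n{i}": rng.normal(0, 1, 16) for i in range(5)})
        with pytest.raises(NoSignificantComboError) as err:
            exhaustive_quadruple_search(df, y)
        assert 0 <= err.value.best_p <= 1

    def test_requires_at_least_four_features(self, rng):
        y = np.array([0, 1] * 10)
        df = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        with pytest.raises(ValueError, match="at least 4"):
            exhaustive_quadruple_search(df, y)
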