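"""Correlation reduction, LASSO selection, RIL scoring, Youden threshold and
the piecewise RIS court-merging rule."""

import numpy as np
import pandas as pd
import pytest

from flairjoint.scoring import (
    LinearScorer,
    fit_lasso_cv,
    merge_ris,
    reduce_by_correlation,
    score_ril,
    subject_ris,
    youden_threshold,
)


def brute_ris(rils, t):
    """Direct evaluation of the piecewise court-merging expression."""
    pos = [r for r in rils if r >= t]
    neg = [r for r in rils if r < t]
    d_pos = sum(abs(r - t) for r in pos)
    d_neg = sum(abs(r - t) for r in neg)
    if d_pos >= d_neg:
        return sum(pos) / len(pos)
    return sum(neg) / len(neg)


def brute_youden(scores, labels):
    """Exhaustive search over midpoint cutoffs for the maximal J."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    cands = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else uniq
    best = None
    for t in cands:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1
        if best is None or (j, sens, -t) > best[0]:
            best = ((j, sens, -t), t)
    return best[1], best[0][0]


class TestCorrelationReduction:
    def test_identical_columns_collapse(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        red = reduce_by_correlation(df, threshold=0.9)
        assert len(red.retained) == 2
        assert "c" in red.retained

    def test_anticorrelated_columns_cluster_together(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "neg_x": -x})
        red = reduce_by_correlation(df, threshold=0.9)
        assert len(red.retained) == 1

    def test_planted_duplicate_pairs(self, rng):
        a = rng.normal(size=80)
        b = rng.normal(size=80)
        c = rng.normal(size=80)
        df = pd.DataFrame(
            {"a": a, "a2": a + 1e-9 * rng.normal(size=80), "b": b, "b2": 2 * b, "c": c}
        )
        red = reduce_by_correlation(df, threshold=0.9)
        assert len(red.retained) == 3

    def test_constant_columns_dropped_with_warning(self, rng):
        df = pd.DataFrame({"k": np.ones(30), "x": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="constant"):
            red = reduce_by_correlation(df, threshold=0.9)
        assert red.retained == ["x"]
        assert red.dropped_constant == ["k"]

    def test_representative_is_highest_variance_member(self, rng):
        x = rng.normal(size=60)
        df = pd.DataFrame({"small": x, "big": 10 * x})
        red = reduce_by_correlation(df, threshold=0.9)
        assert red.retained == ["big"]


class TestLassoCV:
    def test_too_few_samples_for_folds_errors(self, rng):
        x = pd.DataFrame(rng.normal(size=(9, 3)))
        y = np.array([0, 1] * 4 + [0])
        with pytest.raises(ValueError, match="10-fold"):
            fit_lasso_cv(x, y, k=10)

    def test_single_class_errors(self, rng):
        x = pd.DataFrame(rng.normal(size=(20, 3)))
        with pytest.raises(ValueError, match="binary"):
            fit_lasso_cv(x, np.zeros(20), k=5)

    def test_planted_signal_recovered_with_correct_sign(self, rng):
        n = 200
        x = pd.DataFrame(
            rng.normal(size=(n, 20)), columns=[f"f{i}" for i in range(20)]
        )
        logit = 2.0 * x["f3"] - 2.0 * x["f11"]
        y = (logit + rng.logistic(size=n) > 0).astype(int)
        scorer = fit_lasso_cv(x, y, k=5, seed=0)
        assert "f3" in scorer.feature_ids
        assert "f11" in scorer.feature_ids
        w = dict(zip(scorer.feature_ids, scorer.weights))
        assert w["f3"] > 0 > w["f11"]

    def test_null_selects_few(self, rng):
        n = 120
        x = pd.DataFrame(rng.normal(size=(n, 30)))
        x.columns = [f"f{i}" for i in range(30)]
        y = rng.integers(0, 2, size=n)
        scorer = fit_lasso_cv(x, y, k=5, seed=1)
        assert len(scorer.feature_ids) <= 5  # heavy regularisation under the null


class TestRil:
    def test_zero_weights_give_intercept(self):
        scorer = LinearScorer(["a"], [0.0], intercept=0.7, means=[0.0], sds=[1.0])
        assert score_ril(pd.Series({"a": 123.0}), scorer) == pytest.approx(0.7)

    def test_single_feature_arithmetic(self):
        scorer = LinearScorer(["a"], [2.0], intercept=0.0, means=[1.0], sds=[2.0])
        # standardized x = (4 - 1) / 2 = 1.5; RIL = 2 * 1.5 = 3
        assert score_ril(pd.Series({"a": 4.0}), scorer) == pytest.approx(3.0)

    def test_missing_feature_named_in_error(self):
        scorer = LinearScorer(["absent"], [1.0], 0.0, [0.0], [1.0])
        with pytest.raises(KeyError, match="absent"):
            scorer.score(pd.DataFrame({"other": [1.0]}))

    def test_round_trip_on_training_table(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 10)), columns=[f"f{i}" for i in range(10)])
        y = (x["f0"] + 0.5 * rng.normal(size=60) > 0).astype(int)
        scorer = fit_lasso_cv(x, y, k=5, seed=2)
        direct = scorer.score(x)
        again = scorer.score(x.copy())
        np.testing.assert_allclose(direct, again)


class TestYouden:
    def test_separated_midpoint(self):
        t = youden_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.5)

    def test_matches_exhaustive_search_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 40))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            t = youden_threshold(scores, labels)
            t_oracle, j_oracle = brute_youden(scores, labels)
            assert t == pytest.approx(t_oracle)

    def test_all_scores_equal_single_candidate(self):
        t = youden_threshold([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])
        assert t == pytest.approx(1.0)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            youden_threshold([1.0, 2.0], [1, 1])


class TestMergeRis:
    def test_single_lesion_is_its_ril(self):
        assert merge_ris([0.37], 0.5) == pytest.approx(0.37)
        assert merge_ris([0.93], 0.5) == pytest.approx(0.93)

    def test_worked_example_positive_court_wins(self):
        # D+ = |0.8-0.5| + |0.9-0.5| = 0.7 > D- = 0.3 -> mean(0.8, 0.9)
        assert merge_ris([0.2, 0.8, 0.9], 0.5) == pytest.approx(0.85)

    def test_tie_goes_to_positive_court(self):
        # D+ = D- = 0.1 -> positive court wins -> RIS = 0.6
        assert merge_ris([0.4, 0.6], 0.5) == pytest.approx(0.6)

    def test_matches_bruteforce_on_1000_random_instances(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 8))
            rils = rng.normal(size=n)
            t = float(rng.normal())
            assert merge_ris(rils, t) == pytest.approx(brute_ris(rils, t), abs=1e-12)

    def test_order_invariance(self, rng):
        rils = rng.normal(size=6)
        t = 0.1
        for _ in range(10):
            perm = rng.permutation(rils)
            assert merge_ris(perm, t) == pytest.approx(merge_ris(rils, t))

    def test_single_court_limits(self):
        rils = [0.6, 0.7, 0.9]
        assert merge_ris(rils, 0.5) == pytest.approx(np.mean(rils))  # all >= T
        assert merge_ris(rils, 1.0) == pytest.approx(np.mean(rils))  # all < T

    def test_lesion_exactly_at_threshold_joins_positive_court(self):
        # RIL == T contributes 0 distance but enters the positive mean
        assert merge_ris([0.5, 0.9], 0.5) == pytest.approx(0.7)
        # and can drag the positive court to win a tie
        assert merge_ris([0.5], 0.5) == pytest.approx(0.5)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            merge_ris([], 0.5)


def test_subject_ris_groups_by_subject(rng):
    scorer = LinearScorer(["f"], [1.0], 0.0, [0.0], [1.0])
    table = pd.DataFrame(
        {"subject_id": ["s1", "s1", "s2"], "f": [0.2, 0.8, 0.4]}
    )
    ris = subject_ris(table, scorer, threshold=0.5)
    assert ris["s1"] == pytest.approx(0.8)  # D+=0.3 >= D-=0.3 tie -> positive
    assert ris["s2"] == pytest.approx(0.4)
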