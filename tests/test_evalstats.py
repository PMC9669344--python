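"""AUC, DeLong, kappa, Fisher, joint logistic fit and the report layout."""

import numpy as np
import pytest
from scipy import stats

from flairjoint.evalstats import (
    auc,
    classification_metrics,
    cohens_kappa,
    delong_test,
    evaluate,
    fisher_exact,
    fit_joint,
    report_table,
)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 8, 9], [0, 0, 1, 1]) == 1.0

    def test_interleaved_hand_computed(self):
        # concordant pairs 3 of 4 -> 0.75
        assert auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        assert auc(np.exp(s), y) == pytest.approx(auc(s, y))

    def test_negation_complements(self, rng):
        s = rng.normal(size=30)  # continuous: ties almost surely absent
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        assert auc(s, y) + auc(-s, y) == pytest.approx(1.0)


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        s = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        z, p = delong_test(s, s, y)
        assert z == 0.0
        assert p == 1.0

    def test_delta_consistent_with_auc(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        v10a = auc(a, y)
        v10b = auc(b, y)
        z, p = delong_test(a, b, y)
        # reconstruct delta from z * SE: sign must match the AUC difference
        if v10a != v10b:
            assert np.sign(z) == np.sign(v10a - v10b)
        assert 0.0 < p <= 1.0

    def test_matches_paired_bootstrap_oracle(self):
        """DeLong p close to a 10,000-rep paired bootstrap on a fixed instance."""
        rng = np.random.default_rng(60)
        n = 60
        y = np.array([0, 1] * (n // 2))
        signal = rng.normal(size=n)
        a = signal + 0.8 * y + rng.normal(size=n)
        b = signal + 0.4 * y + rng.normal(size=n)
        _z, p = delong_test(a, b, y)
        # bootstrap null distribution of the AUC difference (centred)
        reps = 10_000
        idx = rng.integers(0, n, size=(reps, n))
        deltas = np.empty(reps)
        kept = 0
        for r in range(reps):
            i = idx[r]
            yy = y[i]
            if yy.min() == yy.max():
                continue
            deltas[kept] = auc(a[i], yy) - auc(b[i], yy)
            kept += 1
        deltas = deltas[:kept]
        observed = auc(a, y) - auc(b, y)
        # two-sided bootstrap p: is zero inside the delta distribution?
        p_boot = 2 * min((deltas <= 0).mean(), (deltas >= 0).mean())
        p_boot = min(max(p_boot, 1.0 / reps), 1.0)
        assert p == pytest.approx(p_boot, abs=0.1)


class TestKappa:
    def test_identical_ratings(self):
        assert cohens_kappa([1, 0, 1, 1], [1, 0, 1, 1]) == 1.0

    def test_worked_2x2_table(self):
        # agreement table [[20, 5], [10, 15]] -> p_o 0.7, p_e 0.5, kappa 0.4
        r1 = [0] * 25 + [1] * 25
        r2 = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        assert cohens_kappa(r1, r2) == pytest.approx(0.4)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(99)
        r1 = rng.integers(0, 2, size=10_000)
        r2 = rng.integers(0, 2, size=10_000)
        assert abs(cohens_kappa(r1, r2)) < 0.05

    def test_constant_equal_raters_convention(self):
        assert cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_worked_example_vs_hypergeometric_enumeration(self):
        table = [[1, 9], [11, 3]]
        p = fisher_exact(table)
        # enumeration oracle: sum probabilities of tables as or less likely
        m = stats.hypergeom(24, 10, 12)  # N, K (row1 total), n (col1 total)
        obs = m.pmf(1)
        p_oracle = sum(m.pmf(k) for k in range(0, 11) if m.pmf(k) <= obs + 1e-12)
        assert p == pytest.approx(p_oracle, rel=1e-6)
        assert p == pytest.approx(0.00276, abs=5e-5)

    def test_zero_margin_is_one(self):
        assert fisher_exact([[0, 0], [3, 7]]) == 1.0


class TestJointFit:
    def test_null_coefficients_small(self):
        rng = np.random.default_rng(5)
        n = 500
        ris = rng.normal(size=n)
        sdi = rng.normal(size=n)
        y = rng.integers(0, 2, size=n)
        model = fit_joint(ris, sdi, y)
        assert abs(model.coef_ris) < 0.5
        assert abs(model.coef_sdi) < 0.5
        assert not model.used_fallback

    def test_separation_triggers_finite_fallback(self):
        y = np.array([0] * 10 + [1] * 10)
        model = fit_joint(y.astype(float), y.astype(float), y)
        assert model.used_fallback
        assert np.isfinite([model.coef_ris, model.coef_sdi, model.intercept]).all()

    def test_label_flip_flips_signs(self):
        rng = np.random.default_rng(8)
        n = 300
        ris = rng.normal(size=n)
        sdi = rng.normal(size=n)
        y = ((ris + 0.5 * sdi + rng.logistic(size=n)) > 0).astype(int)
        m1 = fit_joint(ris, sdi, y)
        m2 = fit_joint(ris, sdi, 1 - y)
        assert m1.coef_ris == pytest.approx(-m2.coef_ris, rel=1e-4)
        assert m1.coef_sdi == pytest.approx(-m2.coef_sdi, rel=1e-4)

    def test_wald_p_reported_for_clean_fit(self):
        rng = np.random.default_rng(21)
        n = 200
        ris = rng.normal(size=n)
        sdi = rng.normal(size=n)
        y = ((ris + rng.logistic(size=n)) > 0).astype(int)
        model = fit_joint(ris, sdi, y)
        assert 0 <= model.p_values["ris"] <= 1
        assert model.p_values["sdi"] > 0.001  # noise channel rarely significant


class TestEvaluateReport:
    def _scores(self, rng, n=40, signal=2.0):
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        return {
            "radiomics": rng.normal(size=n) + signal * y,
            "spatial": rng.normal(size=n) + signal * y,
            "joint": rng.normal(size=n) + signal * y,
        }, y

    def test_report_complete_for_three_splits_three_models(self, rng):
        split_scores, split_labels = {}, {}
        for split in ("train", "test", "validation"):
            s, y = self._scores(rng)
            split_scores[split] = s
            split_labels[split] = y
        cutoffs = {m: 1.0 for m in ("radiomics", "spatial", "joint")}
        report = evaluate(split_scores, split_labels, cutoffs)
        assert set(report["splits"]) == {"train", "test", "validation"}
        for entry in report["splits"].values():
            assert set(entry["models"]) == {"radiomics", "spatial", "joint"}
            assert len(entry["delong"]) == 3
        table = report_table(report)
        assert table.shape == (4, 9)

    def test_perfectly_separated_training_accuracy_one(self):
        y = np.array([0] * 10 + [1] * 10)
        scores = y * 10.0
        m = classification_metrics(scores, y, cutoff=5.0)
        assert m["accuracy"] == 1.0
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 1.0

    def test_split_without_both_classes_is_skipped(self, rng):
        s, y = self._scores(rng)
        with pytest.warns(UserWarning, match="lacks both classes"):
            report = evaluate(
                {"train": s, "test": {k: v[:3] for k, v in s.items()}},
                {"train": y, "test": np.ones(3, dtype=int)},
                {m: 0.0 for m in s},
            )
        assert "test" not in report["splits"]
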