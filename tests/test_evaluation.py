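"""ROC / Youden / confusion statistics / chi-squared / DeLong comparison."""

import numpy as np
import pytest

import petresponse as pr


def random_instance(rng, n=None):
    n = n or int(rng.integers(6, 30))
    changes = rng.normal(-20.0, 40.0, size=n).round(1)
    labels = rng.random(n) < 0.5
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    return changes, labels


class TestRoc:
    def test_perfect_separation(self):
        changes = np.array([-80.0, -70.0, -60.0, -10.0, 0.0, 30.0])
        labels = [True, True, True, False, False, False]
        r = pr.roc(changes, labels)
        assert r.auc == 1.0
        assert r.youden_j == 1.0
        assert 10.0 < r.optimal_threshold < 60.0

    def test_all_equal_scores_give_half_auc(self):
        r = pr.roc(np.zeros(10), [True] * 5 + [False] * 5)
        assert r.auc == pytest.approx(0.5)

    def test_auc_equals_trapezoid_and_sklearn_oracles(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(500):
            changes, labels = random_instance(rng)
            r = pr.roc(changes, labels)
            # trapezoidal integration of the empirical curve, traversed in
            # threshold order (ties in the scores make FPR values repeat)
            fpr = 1.0 - r.specificity
            trap = float(np.trapezoid(r.sensitivity[::-1], fpr[::-1]))
            assert r.auc == pytest.approx(trap, abs=1e-12)
            assert r.auc == pytest.approx(
                roc_auc_score(labels, -changes), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            pr.roc([-50.0, -40.0], [True, True])


class TestYoudenOptimal:
    def test_reconstructed_sens_spec_pair(self):
        # printed sensitivity 0.91 and specificity 0.93 combine to J = 0.84
        assert 0.91 + 0.93 - 1.0 == pytest.approx(0.84)

    def test_perfect_test(self):
        r = pr.roc([-80.0, -75.0, 10.0, 20.0], [True, True, False, False])
        _, j = pr.youden_optimal(r)
        assert j == pytest.approx(1.0)

    def test_argmax_matches_exhaustive_scan(self, rng):
        for _ in range(500):
            changes, labels = random_instance(rng)
            r = pr.roc(changes, labels)
            threshold, j = pr.youden_optimal(r)
            scores = -np.asarray(changes)
            pos, neg = scores[labels], scores[~labels]
            best_j = -np.inf
            for c in r.thresholds:
                jj = (pos > c).mean() + (neg <= c).mean() - 1.0
                best_j = max(best_j, jj)
            assert j == pytest.approx(best_j, abs=1e-12)
            # tie-break: no equal-J candidate with smaller magnitude
            for c in r.thresholds:
                jj = (pos > c).mean() + (neg <= c).mean() - 1.0
                if jj == pytest.approx(j, abs=1e-12):
                    assert abs(threshold) <= abs(c) + 1e-12


class TestConfusionStats:
    def test_hand_tabulated_2x2(self):
        s = pr.confusion_stats(tp=8, tn=9, fp=1, fn=2)
        assert s.sensitivity == pytest.approx(0.8)
        assert s.specificity == pytest.approx(0.9)
        assert s.ppv == pytest.approx(8 / 9)
        assert s.npv == pytest.approx(9 / 11)
        assert s.accuracy == pytest.approx(0.85)

    def test_perfect_classifier(self):
        s = pr.confusion_stats(tp=50, tn=50, fp=0, fn=0)
        for v in (s.sensitivity, s.specificity, s.ppv, s.npv, s.accuracy):
            assert v == pytest.approx(1.0)
        assert s.youden_j == pytest.approx(1.0)

    def test_accuracy_identity(self, rng):
        # accuracy = (sens*P + spec*N) / (P + N)
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(1, 60, size=4)
            s = pr.confusion_stats(tp, tn, fp, fn)
            P, N = tp + fn, tn + fp
            assert s.accuracy == pytest.approx(
                (s.sensitivity * P + s.specificity * N) / (P + N)
            )

    def test_undefined_ratios_are_none(self):
        s = pr.confusion_stats(tp=0, tn=5, fp=0, fn=0)
        assert s.sensitivity is None
        assert s.ppv is None
        assert s.specificity == pytest.approx(1.0)


class TestChiSquared:
    def test_balanced_independent_table(self):
        stat, p, sig = pr.chi_squared(25, 25, 25, 25)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert sig is False

    def test_matches_closed_form(self, rng):
        # n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on random tables
        for _ in range(500):
            a, b, c, d = (int(x) for x in rng.integers(1, 80, size=4))
            stat, p, _ = pr.chi_squared(tp=a, fn=b, fp=c, tn=d)
            n = a + b + c + d
            expected = (
                n * (a * d - b * c) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            assert stat == pytest.approx(expected, abs=1e-12 * max(1.0, expected))

    def test_imbalanced_but_independent(self):
        stat, _, _ = pr.chi_squared(tp=40, fn=40, fp=10, tn=10)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_row_column_swap_invariance(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 50, size=4))
            s1, _, _ = pr.chi_squared(tp=a, fn=b, fp=c, tn=d)
            s2, _, _ = pr.chi_squared(tp=d, fn=c, fp=b, tn=a)
            assert s1 == pytest.approx(s2, abs=1e-9)

    def test_zero_marginal_undefined(self):
        stat, p, sig = pr.chi_squared(tp=0, fn=0, fp=10, tn=10)
        assert stat is None and p is None and sig is None


class TestCompareAuc:
    def test_identical_rocs(self, rng):
        changes, labels = random_instance(rng, n=40)
        r = pr.roc(changes, labels)
        z, p = pr.compare_auc(r, r)
        assert z == 0.0
        assert p == 1.0

    def test_separated_vs_uninformative_significant(self, rng):
        n = 200
        labels = np.arange(n) % 2 == 0
        good = np.where(labels, -60.0, 10.0) + rng.normal(0, 8.0, n)
        noise = rng.normal(-25.0, 30.0, n)
        r_good = pr.roc(good, labels)
        r_noise = pr.roc(noise, labels)
        assert r_good.auc > 0.9 > r_noise.auc
        z, p = pr.compare_auc(r_good, r_noise)
        assert p < 0.05

    def test_variance_close_to_bootstrap(self, rng):
        n = 200
        labels = rng.random(n) < 0.5
        labels[:2] = [True, False]
        changes = np.where(labels, -40.0, -10.0) + rng.normal(0, 25.0, n)
        r = pr.roc(changes, labels)
        # bootstrap the AUC difference variance via a second, noisier metric
        other = changes + rng.normal(0, 20.0, n)
        r2 = pr.roc(other, labels)
        z, _ = pr.compare_auc(r, r2)
        diffs = []
        idx = np.arange(n)
        for _ in range(2000):
            take = rng.choice(idx, size=n, replace=True)
            if labels[take].all() or not labels[take].any():
                continue
            d = (
                pr.roc(changes[take], labels[take]).auc
                - pr.roc(other[take], labels[take]).auc
            )
            diffs.append(d)
        boot_var = np.var(diffs)
        delong_var = ((r.auc - r2.auc) / z) ** 2 if z != 0 else np.nan
        assert delong_var == pytest.approx(boot_var, rel=0.2)

    def test_unpaired_rejected(self, rng):
        r1 = pr.roc(*random_instance(rng, n=20))
        r2 = pr.roc(*random_instance(rng, n=22))
        with pytest.raises(ValueError, match="paired"):
            pr.compare_auc(r1, r2)


class TestPercentRow:
    def test_half_up_rounding_of_percentages(self):
        s = pr.confusion_stats(tp=101, tn=92, fp=7, fn=10)
        row = s.as_percent_row()
        assert row["ppv_pct"] == 94  # 101/108 = 93.52%
        assert row["npv_pct"] == 90  # 92/102 = 90.2%
        assert row["accuracy_pct"] == 92
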