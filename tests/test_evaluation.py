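"""Diagnostic-accuracy statistics: AUC, DeLong, exact CIs, calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ba_diag.errors import InputError
from ba_diag.evaluate import (
    auc_statistic,
    calibration,
    cohort_comparison,
    confusion_metrics,
    delong_compare,
    delong_variance,
    format_percent,
    roc_and_auc,
    subgroup_report,
)


def brute_force_auc(scores, labels):
    """Direct cross-class pair counting: concordant + half ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for x in cases:
        for v in controls:
            total += 1.0 if x > v else (0.5 if x == v else 0.0)
    return total / (len(cases) * len(controls))


class TestAuc:
    def test_perfect_separation(self):
        assert auc_statistic([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_four_point_example(self):
        assert auc_statistic([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == 0.75

    def test_all_tied_scores(self):
        assert auc_statistic([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            scores = rng.integers(0, 4, n).astype(float)  # many ties
            labels = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
            rng.shuffle(labels)
            assert auc_statistic(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=200) + np.r_[np.zeros(100), np.ones(100)]
        labels = np.r_[np.zeros(100, int), np.ones(100, int)]
        assert auc_statistic(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a1 = auc_statistic(scores, labels)
        assert auc_statistic(np.exp(scores), labels) == pytest.approx(a1)
        assert auc_statistic(3 * scores - 7, labels) == pytest.approx(a1)

    def test_negation_complement(self, rng):
        scores = rng.integers(0, 5, 40).astype(float)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert auc_statistic(scores, labels) + auc_statistic(-scores, labels) \
            == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            auc_statistic([0.1, 0.9], [1, 1])


class TestDeLong:
    def test_variance_matches_hand_enumerated_structural_components(self):
        # n <= 10: compute V10/V01 by explicit loops and the variance formula
        scores = np.array([0.1, 0.35, 0.35, 0.8, 0.2, 0.5, 0.9, 0.7])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        cases, controls = scores[labels == 1], scores[labels == 0]

        def psi(x, v):
            return 1.0 if x > v else (0.5 if x == v else 0.0)

        v10 = [np.mean([psi(x, v) for v in controls]) for x in cases]
        v01 = [np.mean([psi(x, v) for x in cases]) for v in controls]
        expected_var = (np.var(v10, ddof=1) / len(v10)
                        + np.var(v01, ddof=1) / len(v01))
        auc, var = delong_variance(scores, labels)
        assert auc == pytest.approx(np.mean(v10))
        assert var == pytest.approx(expected_var)

    def test_ci_contains_auc_and_is_truncated(self, rng):
        scores = rng.normal(size=50) + np.r_[np.zeros(25), np.ones(25)] * 3
        labels = np.r_[np.zeros(25, int), np.ones(25, int)]
        out = roc_and_auc(scores, labels)
        lo, hi = out["auc_ci"]
        assert 0.0 <= lo <= out["auc"] <= hi <= 1.0

    def test_identical_scores_p_one(self):
        s = [0.2, 0.4, 0.6, 0.8]
        y = [0, 0, 1, 1]
        out = delong_compare(s, s, y)
        assert out["difference"] == 0.0
        assert out["p_value"] == 1.0

    def test_agrees_with_permutation_oracle(self):
        # paired permutation test: randomly swap the two scores per patient
        g = np.random.default_rng(30)
        n = 30
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        a = g.normal(size=n) + 1.2 * y
        b = g.normal(size=n) + 0.4 * y
        obs = abs(auc_statistic(a, y) - auc_statistic(b, y))
        reps = 20_000
        swap = g.random((reps, n)) < 0.5
        count = 0
        for s in swap:
            aa = np.where(s, b, a)
            bb = np.where(s, a, b)
            if abs(auc_statistic(aa, y) - auc_statistic(bb, y)) >= obs - 1e-12:
                count += 1
        p_perm = count / reps
        p_delong = delong_compare(a, b, y)["p_value"]
        assert p_delong == pytest.approx(p_perm, abs=0.02)

    def test_extreme_effect_small_p(self):
        g = np.random.default_rng(7)
        y = np.r_[np.zeros(100, int), np.ones(100, int)]
        a = y + g.normal(0, 0.05, 200)   # near-perfect
        b = g.normal(0, 1, 200)          # pure noise
        assert delong_compare(a, b, y)["p_value"] < 0.001

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(InputError):
            delong_compare([0.1, 0.2], [0.1], [0, 1])


class TestConfusionMetrics:
    def test_all_correct(self):
        rep = confusion_metrics([True] * 5 + [False] * 5,
                                [1] * 5 + [0] * 5)
        assert rep.sensitivity["percent"] == 100.0
        assert rep.specificity["percent"] == 100.0
        assert rep.accuracy["percent_ci"][1] == 100.0

    def test_counts_and_identities(self, rng):
        calls = rng.random(200) > 0.5
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        rep = confusion_metrics(calls, labels)
        assert rep.tp + rep.fn == (labels == 1).sum()
        assert rep.tn + rep.fp == (labels == 0).sum()
        assert rep.sensitivity["estimate"] == rep.tp / (rep.tp + rep.fn)
        assert rep.accuracy["estimate"] == (rep.tp + rep.tn) / 200
        for m in (rep.sensitivity, rep.specificity, rep.accuracy):
            assert m["ci"][0] <= m["estimate"] <= m["ci"][1]

    def test_clopper_pearson_exact_coverage(self):
        # exact coverage computed by summing the binomial pmf over the k
        # whose interval contains p; must be >= the nominal 95%
        n = 50
        for p in (0.5, 0.9, 0.99):
            k = np.arange(n + 1)
            lo = stats.beta.ppf(0.025, k, n - k + 1)
            hi = stats.beta.ppf(0.975, k + 1, n - k)
            lo[0], hi[n] = 0.0, 1.0
            covered = (lo <= p) & (p <= hi)
            coverage = stats.binom.pmf(k[covered], n, p).sum()
            assert coverage >= 0.95

    def test_rounding_half_away_from_zero(self):
        assert format_percent(0.29945) == 29.9  # 29.945 -> 29.9? no: 29.95->30.0
        assert format_percent(0.2995) == 30.0
        assert format_percent(0.10125, 2) == 10.13

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            confusion_metrics([], [])


class TestCalibration:
    def test_all_ones_single_bin(self):
        cal = calibration([1.0] * 10, [1] * 10)
        assert len(cal) == 1
        assert cal.loc[0, "mean_predicted"] == 1.0
        assert cal.loc[0, "observed_fraction"] == 1.0

    def test_constant_prediction_exact_construction(self):
        probs = [0.3] * 1000
        labels = [1] * 300 + [0] * 700
        cal = calibration(probs, labels)
        assert len(cal) == 1
        assert cal.loc[0, "mean_predicted"] == pytest.approx(0.3)
        assert cal.loc[0, "observed_fraction"] == pytest.approx(0.3)

    def test_counts_sum_to_n(self, rng):
        probs = rng.random(500)
        labels = rng.integers(0, 2, 500)
        cal = calibration(probs, labels)
        assert cal["count"].sum() == 500
        assert cal["observed_fraction"].between(0, 1).all()

    def test_too_few_bins_rejected(self):
        with pytest.raises(InputError):
            calibration([0.5, 0.6], [0, 1], n_bins=1)

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(InputError):
            calibration([1.2], [1])


class TestSubgroupReport:
    def test_single_group_equals_global(self, rng):
        scores = rng.normal(size=100) + np.r_[np.zeros(50), np.ones(50)]
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        from ba_diag.evaluate import evaluate_scores
        rep = subgroup_report(scores, labels, ["all"] * 100, threshold=0.5)
        glob = evaluate_scores(scores, labels, 0.5)
        assert rep["all"].to_dict() == glob.to_dict()

    def test_random_split_groups_agree(self, rng):
        n = 400
        labels = rng.integers(0, 2, n)
        scores = rng.normal(size=n) + 1.5 * labels
        groups = rng.integers(0, 2, n)
        rep = subgroup_report(scores, labels, groups, threshold=0.5)
        a, b = rep["0"], rep["1"]
        assert a.auc_ci[0] <= b.auc <= a.auc_ci[1]
        assert b.auc_ci[0] <= a.auc <= b.auc_ci[1]

    def test_one_class_group_gets_no_auc(self):
        scores = [0.8, 0.9, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        groups = ["cases", "cases", "controls", "controls"]
        with pytest.warns(UserWarning, match="one class"):
            rep = subgroup_report(scores, labels, groups, threshold=0.5)
        assert rep["cases"].auc is None
        assert rep["cases"].sensitivity["estimate"] == 1.0
        assert rep["controls"].specificity["estimate"] == 1.0


class TestCohortComparison:
    def test_identical_tables_maximal_p(self, rng):
        df = pd.DataFrame({
            "sex": rng.choice(["m", "f"], 60),
            "ggt": rng.lognormal(5, 0.5, 60),
        })
        out = cohort_comparison(df, df.copy()).set_index("variable")
        assert (out["p_value"] > 0.95).all()

    def test_chi_squared_two_by_two_hand_statistic(self):
        # (50,50 | 90,10): expected 70/30 per cell block,
        # chi2 = 400*(2/70 + 2/30) = 38.095...
        a = pd.DataFrame({"flag": ["y"] * 50 + ["n"] * 50})
        b = pd.DataFrame({"flag": ["y"] * 90 + ["n"] * 10})
        out = cohort_comparison(a, b)
        expected_stat = 400 * (2 / 70 + 2 / 30)
        p_expected = stats.chi2.sf(expected_stat, 1)
        assert out.loc[0, "p_value"] == pytest.approx(p_expected, rel=1e-9)

    def test_wilcoxon_matches_exact_enumeration_at_tiny_n(self):
        # exact two-sided rank-sum p by enumerating all C(8,4) assignments
        a_vals = [1.2, 3.4, 2.2, 5.0]
        b_vals = [4.1, 6.3, 7.7, 5.5]
        pooled = np.array(a_vals + b_vals)
        ranks = stats.rankdata(pooled)
        obs = ranks[:4].sum()
        mu = ranks.sum() / 2
        count = sum(
            1 for idx in itertools.combinations(range(8), 4)
            if abs(ranks[list(idx)].sum() - mu) >= abs(obs - mu) - 1e-12
        )
        p_exact = count / 70
        out = cohort_comparison(pd.DataFrame({"v": a_vals}),
                                pd.DataFrame({"v": b_vals}))
        assert out.loc[0, "p_value"] == pytest.approx(p_exact, abs=1e-9)

    def test_empty_column_skipped_with_note(self):
        a = pd.DataFrame({"v": [np.nan, np.nan]})
        b = pd.DataFrame({"v": [1.0, 2.0]})
        out = cohort_comparison(a, b)
        assert "skipped" in out.loc[0, "test"]
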