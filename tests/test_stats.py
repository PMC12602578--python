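"""AUC, DeLong, permutation, group-comparison and clinical tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from tlradiomics import (auc, clinical_tests, compare_auc_groups, delong_test,
                         permutation_test)
from tlradiomics.stats import delong_components


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = sum(1.0 if p > n else 0.5 if p == n else 0.0
                for p, n in itertools.product(pos, neg))
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([3.0] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_exhaustive_pair_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.choice(np.linspace(0, 1, 8), size=20)
            labels = rng.integers(0, 2, 20)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_score_negation_complements(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)          # tie-free a.s.
        labels = np.r_[np.ones(12, int), np.zeros(18, int)]
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_identical_scores_degenerate(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
        labels = np.array([0, 0, 1, 1, 1, 0])
        res = delong_test(scores, scores, labels)
        assert res.degenerate
        assert res.z == 0.0 and res.p == 1.0

    def test_auc_equals_mann_whitney_estimator(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a, _, _ = delong_components(scores, labels)
        assert a == pytest.approx(auc(scores, labels), abs=1e-12)

    def test_structural_components_match_placement_definitions(self):
        # V01_i = P-hat(score_i > neg) + 0.5 P-hat(=), per positive sample
        scores = np.array([0.9, 0.3, 0.5, 0.5, 0.1, 0.7])
        labels = np.array([1, 1, 1, 0, 0, 0])
        _, v01, v10 = delong_components(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        for i, s in enumerate(pos):
            expect = np.mean((s > neg) + 0.5 * (s == neg))
            assert v01[i] == pytest.approx(expect, abs=1e-12)
        for j, s in enumerate(neg):
            expect = np.mean((pos > s) + 0.5 * (pos == s))
            assert v10[j] == pytest.approx(expect, abs=1e-12)

    def test_variance_of_auc_against_itself_is_zero(self):
        scores = np.array([0.2, 0.9, 0.4, 0.6, 0.8, 0.1])
        labels = np.array([0, 1, 0, 1, 1, 0])
        res = delong_test(scores, scores, labels)
        assert res.var_diff == 0.0

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(3)
        n, sims = 500, 1000
        labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        rejections = 0
        for _ in range(sims):
            s1 = rng.normal(size=n)
            s2 = rng.normal(size=n)
            if delong_test(s1, s2, labels).p < 0.05:
                rejections += 1
        assert 0.035 <= rejections / sims <= 0.065


def _accuracy_statistic(table, labels):
    """Nearest-centroid training accuracy — a cheap label-dependent
    statistic for permutation testing."""
    x = np.asarray(table, dtype=float)
    labels = np.asarray(labels)
    mu1 = x[labels == 1].mean(axis=0)
    mu0 = x[labels == 0].mean(axis=0)
    pred = (np.linalg.norm(x - mu1, axis=1)
            < np.linalg.norm(x - mu0, axis=1)).astype(int)
    return float((pred == labels).mean())


class TestPermutation:
    def test_label_invariant_statistic_gives_p_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 3))
        labels = rng.integers(0, 2, 30)
        res = permutation_test(lambda t, l: 1.23, x, labels, B=99, seed=0)
        assert res.p == 1.0

    def test_separable_data_gives_minimal_p(self):
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        x = labels[:, None] * 10.0 + np.random.default_rng(5).normal(
            0, 0.01, (20, 1))
        res = permutation_test(_accuracy_statistic, x, labels, B=199, seed=1)
        assert res.p == pytest.approx(1 / 200)

    def test_p_never_zero(self):
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        x = labels[:, None].astype(float)
        res = permutation_test(_accuracy_statistic, x, labels, B=19, seed=2)
        assert res.p > 0

    def test_null_p_values_approximately_uniform(self):
        # a continuous statistic: the class-mean difference (a discrete,
        # heavily tied statistic such as accuracy is valid but
        # conservative, i.e. super-uniform, by construction)
        def mean_diff(table, labels):
            x = np.asarray(table, dtype=float)[:, 0]
            return float(x[labels == 1].mean() - x[labels == 0].mean())

        rng = np.random.default_rng(6)
        pvals = []
        for rep in range(200):
            x = rng.normal(size=(24, 2))
            labels = np.r_[np.ones(12, int), np.zeros(12, int)]
            res = permutation_test(mean_diff, x, labels, B=199,
                                   seed=1000 + rep)
            pvals.append(res.p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_statistic_failure_reports_permutation_index(self):
        calls = {"n": 0}

        def flaky(table, labels):
            calls["n"] += 1
            if calls["n"] > 3:
                raise ValueError("boom")
            return 0.0

        # call 1 is the observed statistic; permutations 0 and 1 succeed
        with pytest.raises(RuntimeError, match="permutation 2"):
            permutation_test(flaky, np.ones((4, 1)),
                             np.array([0, 1, 0, 1]), B=5, seed=0)


class TestCompareAUCGroups:
    def test_identical_level_distributions_give_p_one(self):
        v = np.linspace(0.5, 0.8, 10)
        frame = pd.DataFrame({"feature_type": ["OR"] * 10 + ["TLR"] * 10,
                              "auc_mean": np.r_[v, v]})
        out = compare_auc_groups(frame, "feature_type")
        row = out["pairwise"].iloc[0]
        assert row["p_mannwhitney"] == 1.0
        assert row["mean_diff"] == pytest.approx(0.0)

    def test_power_to_separate_shifted_levels(self):
        rng = np.random.default_rng(7)
        frame = pd.DataFrame({
            "batch_method": ["a"] * 315 + ["b"] * 315,
            "auc_mean": np.r_[rng.normal(0.65, 0.05, 315),
                              rng.normal(0.60, 0.05, 315)]})
        out = compare_auc_groups(frame, "batch_method")
        assert out["pairwise"].iloc[0]["p_welch"] < 0.001
        assert out["summary"].loc["a", "mean_auc"] > \
            out["summary"].loc["b", "mean_auc"]

    def test_single_level_rejected(self):
        frame = pd.DataFrame({"feature_type": ["OR"] * 5,
                              "auc_mean": np.linspace(0.5, 0.9, 5)})
        with pytest.raises(ValueError, match="levels"):
            compare_auc_groups(frame, "feature_type")


class TestClinicalTests:
    def test_balanced_table_not_significant(self):
        meta = pd.DataFrame({
            "outcome": [0, 1] * 40,
            "ER": ([0, 0] * 20 + [1, 1] * 20),
        })
        out = clinical_tests(meta, categorical=("ER",))
        assert out.loc[out["variable"] == "ER", "p"].iloc[0] > 0.9

    def test_strong_association_matches_closed_form_chi_square(self):
        # 2x2 table [[30,10],[10,30]]: chi-square = 20.0 on 1 df
        er = [0] * 40 + [1] * 40
        outcome = [1] * 30 + [0] * 10 + [1] * 10 + [0] * 30
        meta = pd.DataFrame({"outcome": outcome, "ER": er})
        out = clinical_tests(meta, categorical=("ER",))
        from scipy.stats import chi2
        assert out["p"].iloc[0] == pytest.approx(chi2.sf(20.0, 1), rel=1e-6)
        assert out["p"].iloc[0] < 0.001

    def test_constant_variable_skipped(self):
        meta = pd.DataFrame({"outcome": [0, 1, 0, 1], "ER": [1, 1, 1, 1]})
        out = clinical_tests(meta, categorical=("ER",))
        assert out.empty

    def test_continuous_variable_uses_welch(self):
        rng = np.random.default_rng(8)
        meta = pd.DataFrame({"outcome": [0] * 50 + [1] * 50,
                             "age": np.r_[rng.normal(50, 5, 50),
                                          rng.normal(60, 5, 50)]})
        out = clinical_tests(meta, categorical=(), continuous=("age",))
        assert out["test"].iloc[0] == "welch-t"
        assert out["p"].iloc[0] < 1e-6
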