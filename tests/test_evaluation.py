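"""Correlation, ROC/Youden, DeLong, Obuchowski, regression, group summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, rankdata

from hepafat.evaluation import (
    compare_roc_paired,
    fit_steatosis_models,
    group_summaries,
    group_test,
    obuchowski_auc,
    roc_empirical,
    roc_smoothed,
    spearman_rho,
    youden_threshold,
)


def bruteforce_auc(scores, labels):
    """Exhaustive pairwise concordance with ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestSpearman:
    def test_identity_and_reversal(self):
        x = [3.0, 1.0, 7.0, 4.0, 9.0]
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_small_example_matches_rank_formula(self):
        # ranks differ by d = (0, 1, 1, 0): rho = 1 - 6*2/(4*15) = 0.8
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_equals_pearson_of_average_ranks(self, rng):
        for _ in range(20):
            x = rng.integers(0, 6, size=15).astype(float)  # plenty of ties
            y = rng.integers(0, 6, size=15).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rx, ry = rankdata(x), rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestRocEmpirical:
    def test_perfect_separation(self):
        roc = roc_empirical([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(1.0)

    def test_identical_scores_give_half(self):
        roc = roc_empirical([5.0] * 8, [0, 1, 0, 1, 0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_four_point_example(self):
        # pos = {2, 4}, neg = {3, 1}: 3 of 4 pairs concordant
        roc = roc_empirical([3, 1, 2, 4], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(0.75)

    def test_matches_bruteforce_concordance(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 31))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            roc = roc_empirical(scores, labels)
            assert roc.auc == pytest.approx(
                bruteforce_auc(scores, labels), abs=1e-12
            )

    def test_curve_is_monotone(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        roc = roc_empirical(scores, labels)
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_empirical([1, 2, 3], [1, 1, 1])


class TestRocSmoothed:
    def test_small_bandwidth_approaches_empirical(self, rng):
        scores = rng.normal(size=60)
        labels = (scores + 0.8 * rng.normal(size=60) > 0).astype(int)
        emp = roc_empirical(scores, labels)
        smooth = roc_smoothed(scores, labels, bandwidth=1e-4)
        assert smooth.auc == pytest.approx(emp.auc, abs=0.01)

    def test_separated_normals_match_binormal_oracle(self, rng):
        # smoothing in rank space preserves the AUC, which for two normals
        # is Phi(delta / sqrt(s1^2 + s2^2))
        neg = rng.normal(0.0, 1.0, size=300)
        pos = rng.normal(3.5, 1.0, size=300)
        scores = np.concatenate([neg, pos])
        labels = np.array([0] * 300 + [1] * 300)
        roc = roc_smoothed(scores, labels)
        oracle = norm.cdf(3.5 / np.sqrt(2.0))
        assert roc.auc > 0.97
        assert roc.auc == pytest.approx(oracle, abs=0.02)

    def test_identical_distributions_give_half(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        roc = roc_smoothed(scores, labels)
        assert roc.auc == pytest.approx(0.5, abs=0.08)

    def test_degenerate_bandwidth_rejected(self, rng):
        scores = rng.normal(size=20)
        labels = np.array([0, 1] * 10)
        with pytest.raises(ValueError):
            roc_smoothed(scores, labels, bandwidth=-1.0)


class TestYoudenThreshold:
    def test_perfect_separation(self):
        roc = roc_empirical([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        res = youden_threshold(roc)
        assert res.youden_j == pytest.approx(1.0)
        assert 3 < res.threshold <= 10
        assert res.youden_j == pytest.approx(
            res.sensitivity + res.specificity - 1.0, abs=1e-12
        )

    def test_identical_classes_near_zero_j(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        res = youden_threshold(roc_smoothed(scores, labels))
        assert res.youden_j < 0.25

    def test_equals_exhaustive_maximum(self, rng):
        scores = np.round(rng.normal(size=30), 1)
        labels = (scores + rng.normal(size=30) > 0).astype(int)
        roc = roc_empirical(scores, labels)
        res = youden_threshold(roc)
        best = max(
            np.mean(scores[labels == 1] >= t) - np.mean(scores[labels == 0] >= t)
            for t in np.unique(scores)
        )
        assert res.youden_j == pytest.approx(best, abs=1e-12)

    def test_binormal_threshold_near_equal_likelihood_point(self, rng):
        # equal variances: the J-maximizing threshold is the midpoint of means
        neg = rng.normal(0.0, 1.0, size=500)
        pos = rng.normal(2.0, 1.0, size=500)
        scores = np.concatenate([neg, pos])
        labels = np.array([0] * 500 + [1] * 500)
        res = youden_threshold(roc_smoothed(scores, labels))
        assert res.threshold == pytest.approx(1.0, abs=0.3)


class TestCompareRocPaired:
    def test_identical_scores_give_p_one(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        assert compare_roc_paired(scores, scores, labels) == 1.0

    def test_power_against_random_marker(self, rng):
        # strong vs uninformative marker at n = 200: p < 0.01 nearly always
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            latent = rng.normal(size=200)
            labels = (latent > 0).astype(int)
            strong = latent + 0.3 * rng.normal(size=200)
            random_marker = rng.normal(size=200)
            if compare_roc_paired(strong, random_marker, labels) < 0.01:
                rejections += 1
        assert rejections >= 95

    def test_type_i_error_calibrated(self, rng):
        # two equally informative correlated markers: ~5% rejections at 0.05
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            latent = rng.normal(size=120)
            labels = (latent > 0).astype(int)
            a = latent + rng.normal(size=120)
            b = latent + rng.normal(size=120)
            if compare_roc_paired(a, b, labels) < 0.05:
                hits += 1
        assert 0.03 <= hits / n_rep <= 0.07

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            compare_roc_paired([1, 2], [2, 1], [1, 1])


class TestObuchowski:
    def test_perfect_ordinal_predictor(self):
        truth = [0, 0, 1, 1, 2, 2]
        pred = [0.1, 0.2, 1.1, 1.4, 2.2, 2.9]
        auc, se = obuchowski_auc(pred, truth)
        assert auc == pytest.approx(1.0)

    def test_independent_predictor_near_half(self, rng):
        truth = np.repeat([0, 1, 2, 3], 50)
        pred = rng.normal(size=200)
        auc, _ = obuchowski_auc(pred, truth)
        assert auc == pytest.approx(0.5, abs=0.08)

    def test_six_subject_exhaustive_oracle(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        pred = np.array([1.0, 2.5, 2.0, 3.0, 2.8, 4.0])
        # brute force: average concordance over all between-level pairs
        num, count = 0.0, 0
        for i, j in itertools.combinations(range(6), 2):
            if truth[i] == truth[j]:
                continue
            lo, hi = (i, j) if truth[i] < truth[j] else (j, i)
            num += 1.0 if pred[hi] > pred[lo] else (0.5 if pred[hi] == pred[lo] else 0.0)
            count += 1
        auc, se = obuchowski_auc(pred, truth)
        assert auc == pytest.approx(num / count, abs=1e-12)
        assert se > 0

    def test_two_levels_reduces_to_empirical_auc(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            pred = np.round(rng.normal(size=n), 1)
            truth = rng.integers(0, 2, size=n)
            if truth.sum() in (0, n):
                continue
            auc, _ = obuchowski_auc(pred, truth)
            assert auc == pytest.approx(
                roc_empirical(pred, truth).auc, abs=1e-12
            )

    def test_grade_strings_accepted(self):
        auc, _ = obuchowski_auc(
            [1.0, 2.0, 3.0, 4.0], ["none", "mild", "moderate", "severe"]
        )
        assert auc == pytest.approx(1.0)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            obuchowski_auc([1.0, 2.0], [1, 1])


def _toy_cohort(n=80, seed=0, slope=30.0, noise=0.0):
    rng = np.random.default_rng(seed)
    pdff_pct = rng.uniform(0, 100.0 / slope * 30, size=n)
    histo = slope * pdff_pct / 100.0 + noise * rng.normal(size=n)
    histo = np.clip(histo, 0, 100)
    grade = pd.cut(histo, [-0.1, 5, 33, 66, 101],
                   labels=["none", "mild", "moderate", "severe"]).astype(str)
    return pd.DataFrame(
        {
            "histo_pct": histo,
            "triple_pdff_pct": pdff_pct,
            "grade": grade,
            "nash_flag": rng.integers(0, 2, size=n),
            "fibrosis_stage": rng.choice(["F0", "F1", "F2", "F3", "F4"], size=n),
        }
    )


class TestSteatosisModels:
    def test_exact_linear_data(self):
        cohort = _toy_cohort(noise=0.0)
        fit = fit_steatosis_models(cohort, "triple")
        slope = fit.coefficients.set_index("term").loc["triple", "estimate"]
        assert slope == pytest.approx(30.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_irrelevant_covariate_never_lowers_r2(self):
        cohort = _toy_cohort(noise=8.0)
        base = fit_steatosis_models(cohort, "triple")
        with_cov = fit_steatosis_models(cohort, "triple",
                                        covariates=("nash", "fibrosis"))
        assert with_cov.r_squared >= base.r_squared - 1e-12
        terms = set(with_cov.coefficients["term"])
        assert {"nash", "fibrosis_1", "fibrosis_2", "fibrosis_3or4"} <= terms

    def test_empty_factor_level_dropped_with_warning(self):
        cohort = _toy_cohort(noise=8.0)
        cohort["fibrosis_stage"] = "F0"
        with pytest.warns(UserWarning):
            fit = fit_steatosis_models(cohort, "triple", covariates=("fibrosis",))
        assert not any(
            t.startswith("fibrosis") for t in fit.coefficients["term"]
        )

    def test_interval_coverage_of_null_covariate(self, rng):
        # a covariate with zero true effect: its 95% CI covers 0 in ~95% of
        # repetitions
        n, n_rep, covered = 5000, 200, 0
        for rep in range(n_rep):
            pdff = rng.uniform(0, 35, size=n)
            nash = rng.integers(0, 2, size=n)
            histo = 30 * pdff / 100 * 3 + rng.normal(scale=8, size=n)
            cohort = pd.DataFrame(
                {
                    "histo_pct": histo,
                    "triple_pdff_pct": pdff,
                    "nash_flag": nash,       # no true effect
                    "fibrosis_stage": "F0",
                    "grade": np.where(histo < 5, "none", "mild"),
                }
            )
            fit = fit_steatosis_models(cohort, "triple", covariates=("nash",),
                                       compute_auc=False)
            row = fit.coefficients.set_index("term").loc["nash"]
            if row["ci_low"] <= 0.0 <= row["ci_high"]:
                covered += 1
        assert 0.92 <= covered / n_rep <= 0.98


class TestGroupStatistics:
    def test_quantile_rule(self):
        cohort = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0], "grade": ["mild"] * 4})
        out = group_summaries(cohort, "v")
        row = out.iloc[0]
        assert row["median"] == pytest.approx(2.5)
        assert row["q25"] == pytest.approx(1.75)
        assert row["q75"] == pytest.approx(3.25)

    def test_identical_groups_not_significant(self):
        values = list(range(10))
        assert group_test(values, values) > 0.9

    def test_disjoint_support_highly_significant(self):
        a = np.arange(10.0)
        b = np.arange(100.0, 110.0)
        assert group_test(a, b) < 1e-3

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_test([1.0], [1.0, 2.0])
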