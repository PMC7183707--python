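"""Evaluation statistics: confusion metrics, ROC/AUC, DeLong, rank tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

import ovatriage as ov


def brute_force_auc(scores, outcomes):
    """Exhaustive positive-negative pair counting with half credit for ties."""
    pos = [s for s, o in zip(scores, outcomes) if o]
    neg = [s for s, o in zip(scores, outcomes) if not o]
    total = sum(
        1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
    )
    return total / (len(pos) * len(neg))


class TestBinaryOutcome:
    @pytest.mark.parametrize(
        "histology, expected",
        [
            (ov.Histology.BENIGN, False),
            (ov.Histology.BORDERLINE, False),  # borderline groups with benign
            (ov.Histology.MALIGNANT, True),
        ],
    )
    def test_borderline_grouped_with_benign(self, record_factory, histology, expected):
        assert ov.binary_outcome(record_factory(histology=histology)) is expected


class TestConfusion:
    def test_all_negative_low_risk(self):
        counts = ov.tabulate_confusion([False] * 6, [ov.Risk.LOW] * 6)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (0, 0, 0, 6)

    def test_reference_cohort_structure(self):
        """27 positives of which 17 high risk, 128 negatives of which 8 high."""
        outcomes = [True] * 27 + [False] * 128
        classifications = (
            [ov.Risk.HIGH] * 17 + [ov.Risk.LOW] * 10
            + [ov.Risk.HIGH] * 8 + [ov.Risk.LOW] * 120
        )
        counts = ov.tabulate_confusion(outcomes, classifications)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (17, 10, 8, 120)

    def test_three_record_toy(self):
        counts = ov.tabulate_confusion(
            [True, False, True], [ov.Risk.HIGH, ov.Risk.LOW, ov.Risk.LOW]
        )
        assert (counts.tp, counts.tn, counts.fn, counts.fp) == (1, 1, 1, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ov.tabulate_confusion([True], [ov.Risk.HIGH, ov.Risk.LOW])

    def test_partition_additivity(self):
        rng = np.random.default_rng(11)
        outcomes = list(rng.random(80) < 0.3)
        cls = [ov.Risk.HIGH if b else ov.Risk.LOW for b in rng.random(80) < 0.4]
        whole = ov.tabulate_confusion(outcomes, cls)
        split = rng.random(80) < 0.5
        part_a = ov.tabulate_confusion(
            [o for o, s in zip(outcomes, split) if s],
            [c for c, s in zip(cls, split) if s],
        )
        part_b = ov.tabulate_confusion(
            [o for o, s in zip(outcomes, split) if not s],
            [c for c, s in zip(cls, split) if not s],
        )
        assert part_a + part_b == whole


class TestPerformanceMetrics:
    def test_point_estimates_are_exact_ratios(self):
        counts = ov.ConfusionCounts(tp=17, fn=10, fp=8, tn=120)
        perf = ov.performance_metrics(counts)
        assert perf.sensitivity.value == pytest.approx(100 * 17 / 27)
        assert perf.specificity.value == pytest.approx(100 * 120 / 128)
        assert perf.ppv.value == pytest.approx(100 * 17 / 25)
        assert perf.npv.value == pytest.approx(100 * 120 / 130)

    def test_ppv_example(self):
        perf = ov.performance_metrics(ov.ConfusionCounts(tp=18, fp=14, fn=9, tn=114))
        # printed as 56.3 under half-up display rounding of 56.25
        assert perf.ppv.value == pytest.approx(56.3, abs=0.05)

    def test_perfect_classifier(self):
        perf = ov.performance_metrics(ov.ConfusionCounts(tp=20, fp=0, fn=0, tn=30))
        for est in (perf.sensitivity, perf.specificity, perf.ppv, perf.npv):
            assert est.value == 100.0
            assert est.ci_high == 100.0

    def test_wilson_cis_are_ordered_and_bounded(self):
        perf = ov.performance_metrics(ov.ConfusionCounts(tp=1, fp=1, fn=1, tn=1))
        for est in (perf.sensitivity, perf.specificity, perf.ppv, perf.npv):
            assert 0.0 <= est.ci_low <= est.value <= est.ci_high <= 100.0
            assert est.ci_low < est.ci_high

    def test_undefined_ppv_marked_not_nan(self):
        # everything called low risk: no predicted positives
        perf = ov.performance_metrics(ov.ConfusionCounts(tp=0, fp=0, fn=5, tn=10))
        assert perf.ppv is None
        assert perf.npv is not None

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="sensitivity"):
            ov.performance_metrics(ov.ConfusionCounts(tp=0, fp=2, fn=0, tn=8))


class TestRoc:
    def test_perfect_separation_passes_through_corner(self):
        curve = ov.empirical_roc([3.0, 2.0, 1.0, 0.5], [True, True, False, False])
        assert any(f == 0.0 and t == 1.0 for f, t in zip(curve.fpr, curve.tpr))

    def test_constant_scores_collapse_to_diagonal(self):
        curve = ov.empirical_roc([1.0] * 6, [True, False, True, False, False, True])
        assert len(curve.fpr) == 2  # anchor plus the single tied jump
        assert ov.auc([1.0] * 6, [True, False, True, False, False, True]) == 0.5

    def test_four_point_toy_staircase(self):
        scores = [0.9, 0.4, 0.6, 0.1]
        outcomes = [True, True, False, False]
        curve = ov.empirical_roc(scores, outcomes)
        assert list(curve.thresholds) == [np.inf, 0.9, 0.6, 0.4, 0.1]
        assert list(curve.tpr) == [0.0, 0.5, 0.5, 1.0, 1.0]
        assert list(curve.fpr) == [0.0, 0.0, 0.5, 0.5, 1.0]
        assert ov.auc(scores, outcomes) == 0.75  # 3 of 4 concordant pairs

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ov.empirical_roc([1.0, 2.0], [True, True])

    def test_auc_equals_exhaustive_pair_counting(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            outcomes = rng.random(n) < 0.4
            if outcomes.all() or not outcomes.any():
                continue
            assert ov.auc(scores, outcomes) == brute_force_auc(scores, outcomes)

    def test_auc_matches_sklearn(self):
        """Independent library cross-check of the rank-based AUC."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            scores = np.round(rng.normal(size=60), 1)
            outcomes = rng.random(60) < 0.3
            if outcomes.all() or not outcomes.any():
                continue
            assert ov.auc(scores, outcomes) == pytest.approx(
                roc_auc_score(outcomes, scores), abs=1e-12
            )

    def test_trapezoid_under_curve_equals_auc(self):
        rng = np.random.default_rng(8)
        scores = np.round(rng.normal(size=80), 1)
        outcomes = rng.random(80) < 0.4
        curve = ov.empirical_roc(scores, outcomes)
        assert np.trapezoid(curve.tpr, curve.fpr) == pytest.approx(
            ov.auc(scores, outcomes), abs=1e-12
        )

    @given(st.integers(0, 2**32 - 1))
    def test_monotone_transform_invariance_and_label_flip(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        outcomes = np.r_[np.ones(10), np.zeros(20)].astype(bool)
        a = ov.auc(scores, outcomes)
        assert ov.auc(np.exp(scores), outcomes) == pytest.approx(a, abs=1e-12)
        assert ov.auc(scores, ~outcomes) == pytest.approx(1.0 - a, abs=1e-12)


class TestDeLong:
    def test_perfect_separation_degenerate_ci(self):
        est = ov.delong_ci([4.0, 3.0, 1.0, 0.5], [True, True, False, False])
        assert est.auc == 1.0
        assert est.se == 0.0
        assert est.ci95 == (1.0, 1.0)

    def _fixture(self):
        # frozen dataset: 18 positives, 27 negatives, two correlated scores
        rng = np.random.default_rng(20240101)
        y = np.r_[np.ones(18), np.zeros(27)].astype(bool)
        a = np.round(np.r_[rng.normal(1.2, 1.0, 18), rng.normal(0, 1.0, 27)], 3)
        b = np.round(0.6 * a + np.round(rng.normal(0, 0.8, 45), 3), 3)
        return y, a, b

    def test_ci_matches_proc_reference(self):
        """CI cross-validated against the pROC reference implementation."""
        y, a, b = self._fixture()
        est_a = ov.delong_ci(a, y)
        assert est_a.auc == pytest.approx(0.7366255144, abs=1e-9)
        assert est_a.ci95[0] == pytest.approx(0.5775555441, abs=1e-9)
        assert est_a.ci95[1] == pytest.approx(0.8956954847, abs=1e-9)
        est_b = ov.delong_ci(b, y)
        assert est_b.auc == pytest.approx(0.6152263374, abs=1e-9)
        assert est_b.ci95[0] == pytest.approx(0.4493885001, abs=1e-9)
        assert est_b.ci95[1] == pytest.approx(0.7810641748, abs=1e-9)

    def test_paired_test_matches_proc_reference(self):
        y, a, b = self._fixture()
        diff, z, p = ov.delong_paired_test(a, b, y)
        assert diff == pytest.approx(0.7366255144 - 0.6152263374, abs=1e-9)
        assert z == pytest.approx(1.7058741623, abs=1e-9)
        assert p == pytest.approx(0.0880315113, abs=1e-9)

    def test_ci_close_to_bootstrap(self):
        """Normal-theory DeLong CI near a percentile bootstrap on a small set."""
        y, a, _ = self._fixture()
        est = ov.delong_ci(a, y)
        rng = np.random.default_rng(99)
        pos, neg = a[y], a[~y]
        boots = [
            ov.auc(
                np.r_[rng.choice(pos, pos.size), rng.choice(neg, neg.size)],
                np.r_[np.ones(pos.size), np.zeros(neg.size)].astype(bool),
            )
            for _ in range(2000)
        ]
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert est.ci95[0] == pytest.approx(lo, abs=0.05)
        assert est.ci95[1] == pytest.approx(hi, abs=0.05)

    def test_score_against_itself(self):
        y, a, _ = self._fixture()
        diff, z, p = ov.delong_paired_test(a, a, y)
        assert diff == 0.0
        assert p == 1.0

    def test_rank_invariance_of_paired_difference(self):
        y, a, _ = self._fixture()
        diff, _, p = ov.delong_paired_test(a, np.exp(a), y)
        assert diff == 0.0
        assert p == 1.0

    def test_paired_p_agrees_with_permutation_oracle(self):
        """Swap-permutation null of the AUC difference on a fixed cohort."""
        y, a, b = self._fixture()
        observed = abs(ov.auc(a, y) - ov.auc(b, y))
        rng = np.random.default_rng(123)
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            swap = rng.random(y.size) < 0.5
            pa = np.where(swap, b, a)
            pb = np.where(swap, a, b)
            if abs(ov.auc(pa, y) - ov.auc(pb, y)) >= observed - 1e-12:
                count += 1
        p_perm = count / n_perm
        _, _, p_delong = ov.delong_paired_test(a, b, y)
        assert p_delong == pytest.approx(p_perm, abs=0.03)

    def test_degenerate_class_sizes_rejected(self):
        with pytest.raises(ValueError, match="2 positives"):
            ov.delong_ci([1.0, 2.0, 3.0], [True, False, False])


class TestRankAndAssociation:
    def test_identical_singletons_no_evidence(self):
        _, p = ov.mann_whitney_test([1.0], [1.0])
        assert p == 1.0

    def test_fully_separated_small_groups(self):
        u, p = ov.mann_whitney_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-9)  # exact: 2/C(6,3)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ov.mann_whitney_test([], [1.0])

    def test_proportional_table_statistic_zero(self):
        stat, df, p = ov.chi_square_test([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_diagonal_two_by_two(self):
        stat, df, p = ov.chi_square_test([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            ov.chi_square_test([[0, 0], [5, 5]])


class TestGroupSummaryAndSubgroups:
    def test_single_record_stratum(self, record_factory):
        cohort = [record_factory(histology=ov.Histology.MALIGNANT, he4=90.0,
                                 epithelial=False)]
        summary = ov.group_summary(cohort, "he4")
        mal = summary["malignant"]
        assert mal["median"] == mal["min"] == mal["max"] == 90.0
        assert summary["benign"] is None  # empty stratum absent, not zero

    def test_median_by_sort_oracle(self, record_factory):
        he4s = [80.0, 30.0, 55.0, 41.0, 62.0]
        cohort = [record_factory(id=f"r{i}", he4=v) for i, v in enumerate(he4s)]
        summary = ov.group_summary(cohort, "he4")["benign"]
        assert summary["median"] == sorted(he4s)[2]
        assert (summary["min"], summary["max"]) == (30.0, 80.0)

    def test_identity_filter_matches_unfiltered(self, small_cohort):
        perf_all, auc_all, counts_all = ov.evaluate_subgroup(small_cohort, "roma", "all")
        outcomes = [ov.binary_outcome(r) for r in small_cohort]
        scores = [ov.test_score(r, "roma") for r in small_cohort]
        assert auc_all.auc == pytest.approx(ov.auc(scores, outcomes))
        assert counts_all.positives == sum(outcomes)

    def test_menopausal_partition_sums_to_overall(self, small_cohort):
        for test in ov.TEST_NAMES:
            _, _, pre = ov.evaluate_subgroup(small_cohort, test, "premenopausal")
            _, _, post = ov.evaluate_subgroup(small_cohort, test, "postmenopausal")
            _, _, whole = ov.evaluate_subgroup(small_cohort, test, "all")
            assert pre + post == whole

    def test_epithelial_only_keeps_all_negatives(self, small_cohort):
        _, _, counts = ov.evaluate_subgroup(small_cohort, "roma", "epithelial_only")
        _, _, whole = ov.evaluate_subgroup(small_cohort, "roma", "all")
        assert counts.negatives == whole.negatives
        assert counts.positives == sum(
            1 for r in small_cohort
            if r.histology is ov.Histology.MALIGNANT and r.epithelial
        )

    def test_epithelial_ordering_raises_sensitivity(self, record_factory):
        """When epithelial positives outscore the rest, restricting to them
        cannot lower sensitivity."""
        cohort = [
            record_factory(id=f"n{i}", he4=30.0 + i) for i in range(20)
        ] + [
            record_factory(id=f"e{i}", he4=200.0 + i,
                           histology=ov.Histology.MALIGNANT, epithelial=True)
            for i in range(5)
        ] + [
            record_factory(id=f"m{i}", he4=70.0 + i,
                           histology=ov.Histology.MALIGNANT, epithelial=False)
            for i in range(5)
        ]
        perf_epi, _, _ = ov.evaluate_subgroup(cohort, "he4", "epithelial_only")
        perf_all, _, _ = ov.evaluate_subgroup(cohort, "he4", "all")
        assert perf_epi.sensitivity.value >= perf_all.sensitivity.value

    def test_emptying_filter_is_an_explicit_error(self, record_factory):
        cohort = [record_factory(id=f"b{i}") for i in range(5)] + [
            record_factory(id="m0", histology=ov.Histology.MALIGNANT,
                           epithelial=False, he4=90.0)
        ]
        with pytest.raises(ValueError, match="positive"):
            ov.evaluate_subgroup(cohort, "he4", "epithelial_only")

    def test_unknown_subgroup_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="subgroup"):
            ov.evaluate_subgroup(small_cohort, "he4", "nope")


class TestEvaluateCohort:
    def test_full_results_structure(self, small_cohort):
        results = ov.evaluate_cohort(small_cohort)
        assert set(results["subgroups"]) == set(ov.SUBGROUP_FILTERS)
        assert set(results["medians"]) == set(ov.TEST_NAMES)
        assert len(results["auc_comparisons"]) == 15
        for res in results["auc_comparisons"].values():
            assert 0.0 <= res["p"] <= 1.0

    def test_bonferroni_only_raises_p(self, small_cohort):
        plain = ov.evaluate_cohort(small_cohort)
        adj = ov.evaluate_cohort(small_cohort, bonferroni=True)
        for pair in plain["auc_comparisons"]:
            assert adj["auc_comparisons"][pair]["p"] >= plain["auc_comparisons"][pair]["p"]
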