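"""Unit and property tests for the localisation statistics."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from ezmap.stats import (
    PatientOutcomeRecord,
    TwoByTwoTable,
    classify_tendency,
    compute_drs,
    exact_binomial_p,
    fit_two_cut_tree,
    loocv_tree,
    odds_ratio_ci,
    outcome_auc,
    rank_regions_for_implantation,
    svm_separability,
    yates_chi_square,
)


def brute_force_drs(scores, resected):
    """Independent pairwise oracle: loop over all (resected, spared) pairs."""
    r = [s for s, f in zip(scores, resected) if f]
    s = [v for v, f in zip(scores, resected) if not f]
    total = 0.0
    for rv in r:
        for sv in s:
            if sv > rv:
                total += 1.0
            elif sv == rv:
                total += 0.5
    return total / (len(r) * len(s))


class TestDrs:
    @pytest.mark.parametrize(
        "scores, resected, expected",
        [
            ([3, 2, 1, 0], [True, True, False, False], 0.0),  # largest all resected
            ([0, 1, 2], [True, False, False], 1.0),  # largest all spared
            ([2, 0, 1], [True, True, False], 0.5),  # 1>2 false, 1>0 true
        ],
    )
    def test_closed_form_extremes(self, scores, resected, expected):
        assert compute_drs(scores, resected) == expected

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 31))
            scores = rng.choice([-2.0, -1.0, 0.0, 0.5, 1.0, 2.0, 3.0], size=n)
            resected = rng.random(n) < 0.4
            if resected.all() or not resected.any():
                continue
            assert compute_drs(scores, resected) == pytest.approx(
                brute_force_drs(scores, resected), abs=1e-12
            )

    def test_u_statistic_relation(self, rng):
        """D_RS * n_R * n_S equals the classical rank-sum U statistic."""
        for _ in range(30):
            n = int(rng.integers(4, 25))
            scores = rng.normal(size=n)
            resected = np.zeros(n, dtype=bool)
            resected[: int(rng.integers(1, n))] = True
            rng.shuffle(resected)
            if resected.all() or not resected.any():
                continue
            nr, ns = resected.sum(), (~resected).sum()
            u = mannwhitneyu(
                scores[~resected], scores[resected], alternative="two-sided"
            ).statistic
            assert compute_drs(scores, resected) * nr * ns == pytest.approx(u)

    def test_negation_maps_to_complement(self, rng):
        scores = rng.normal(size=15)
        resected = np.arange(15) < 6
        d = compute_drs(scores, resected)
        assert compute_drs(-scores, resected) == pytest.approx(1.0 - d)

    def test_degenerate_groups_raise(self):
        with pytest.raises(ValueError):
            compute_drs([1.0, 2.0], [True, True])


class TestOutcomeAuc:
    def test_perfect_ordering(self):
        auc, _ = outcome_auc([0.1, 0.2, 0.8, 0.9], [True, True, False, False])
        assert auc == 1.0

    def test_shared_kernel_symmetry(self, rng):
        """AUC(x) + AUC(-x) = 1 with symmetric tie handling."""
        x = rng.choice([0.0, 0.25, 0.5, 0.5, 1.0], size=16)
        y = rng.random(16) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        a1, _ = outcome_auc(x, y)
        a2, _ = outcome_auc(-x, y)
        assert a1 + a2 == pytest.approx(1.0)

    def test_matches_pair_count_oracle(self, rng):
        x = rng.normal(size=16)
        y = np.arange(16) < 8
        auc, _ = outcome_auc(x, y)
        # brute force: fraction of (sf, nsf) pairs with nsf value larger
        cnt = sum(
            1.0 if xn > xs else 0.5 if xn == xs else 0.0
            for xs in x[y]
            for xn in x[~y]
        )
        assert auc == pytest.approx(cnt / 64)


class TestSvmSeparability:
    def test_dominating_resected_is_separable_toward_top_right(self):
        resected = [(2.0, 2.0), (3.0, 2.5), (2.5, 3.0)]
        spared = [(0.0, 0.0), (0.5, 0.2), (0.1, 0.6)]
        sep, maximal = svm_separability(
            resected + spared, [True] * 3 + [False] * 3
        )
        assert sep and maximal == "resected"

    def test_mirror_labels_flip_the_call(self):
        resected = [(0.0, 0.0), (0.5, 0.2), (0.1, 0.6)]
        spared = [(2.0, 2.0), (3.0, 2.5), (2.5, 3.0)]
        sep, maximal = svm_separability(
            resected + spared, [True] * 3 + [False] * 3
        )
        assert sep and maximal == "spared"

    def test_alternating_collinear_points_not_separable(self):
        pts = [(float(i), float(i)) for i in range(4)]
        labels = [True, False, True, False]
        # exhaustive half-plane check: no consistent linear separator exists
        for w1, w2, b in itertools.product(np.linspace(-2, 2, 9), repeat=3):
            side = [w1 * x + w2 * y + b > 0 for x, y in pts]
            assert side != labels or len(set(side)) == 1
        sep, maximal = svm_separability(pts, labels)
        assert not sep and maximal == "undefined"

    def test_duplicate_point_in_both_classes(self):
        pts = [(0.0, 0.0), (0.0, 0.0), (1.0, 1.0), (2.0, 2.0)]
        sep, _ = svm_separability(pts, [True, False, True, False])
        assert not sep

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            svm_separability([(0, 0), (1, 1), (2, 2)], [True, False, False])


class TestContingency:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((12, 13, 13, 5), 1.63),  # sex split by outcome
            ((15, 10, 6, 12), 2.01),  # side of surgery
            ((16, 9, 10, 8), 0.06),  # temporal vs extratemporal
            ((10, 15, 10, 8), 0.49),  # MRI lesional status
        ],
    )
    def test_corrected_chi_square_on_cohort_tables(self, cells, expected):
        chi2, p = yates_chi_square(TwoByTwoTable(*cells))
        assert chi2 == pytest.approx(expected, abs=0.005)
        assert 0 < p < 1

    def test_correction_clamps_null_table(self):
        chi2, p = yates_chi_square(TwoByTwoTable(5, 5, 5, 5))
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_corrected_never_exceeds_uncorrected(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 30, size=4)
            t = TwoByTwoTable(int(a), int(b), int(c), int(d))
            chi2, _ = yates_chi_square(t)
            n = t.n
            uncorr = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert chi2 <= uncorr + 1e-12

    def test_odds_ratio_separable_cohort_table(self):
        or_, lo, hi = odds_ratio_ci(TwoByTwoTable(12, 4, 2, 10))
        assert or_ == pytest.approx(15.0)
        assert lo == pytest.approx(2.26, abs=0.005)
        assert hi == pytest.approx(99.64, abs=0.005)

    def test_odds_ratio_null_and_simple_tables(self):
        or_, lo, hi = odds_ratio_ci(TwoByTwoTable(1, 1, 1, 1))
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)  # symmetric about 1 on log scale
        assert odds_ratio_ci(TwoByTwoTable(2, 1, 1, 2))[0] == pytest.approx(4.0)

    def test_degenerate_table_uses_continuity_fallback(self):
        or_, lo, hi = odds_ratio_ci(TwoByTwoTable(10, 0, 0, 0))
        assert np.isfinite(or_) and np.isfinite(hi) and lo > 0

    def test_exact_binomial_two_sided(self):
        # 11 of 15 non-separable patients seizure-free
        assert exact_binomial_p(11, 15) == pytest.approx(2 * 1941 / 32768)

    def test_classify_tendency_crosstab(self):
        records = []
        layout = [("resected", True, 12), ("resected", False, 4), ("spared", True, 2), ("spared", False, 10)]
        i = 0
        for maximal, sf, n in layout:
            for _ in range(n):
                records.append(
                    PatientOutcomeRecord(
                        patient_id=f"p{i}",
                        drs_conn=0.5,
                        drs_ieeg=0.5,
                        separable=True,
                        maximal_resected=maximal,
                        ilae=1 if sf else 4,
                    )
                )
                i += 1
        for sf, n in ((True, 11), (False, 4)):
            for _ in range(n):
                records.append(
                    PatientOutcomeRecord(
                        patient_id=f"p{i}",
                        drs_conn=0.5,
                        drs_ieeg=0.5,
                        separable=False,
                        maximal_resected="undefined",
                        ilae=1 if sf else 4,
                    )
                )
                i += 1
        rep = classify_tendency(records)
        assert (rep.table.a, rep.table.b, rep.table.c, rep.table.d) == (12, 4, 2, 10)
        assert rep.odds_ratio == pytest.approx(15.0)
        assert rep.n_separable == 28
        assert rep.nonseparable_binomial_p == pytest.approx(0.1185, abs=5e-4)
        assert rep.chi2_p == pytest.approx(0.0075, abs=5e-4)


def _single_cut_best_accuracy(pts, y):
    """Oracle: best training accuracy attainable with one axis-aligned cut."""
    best = max(np.mean(y), np.mean(~y))
    for axis in (0, 1):
        v = pts[:, axis]
        for t in np.unique(v):
            for below_label in (True, False):
                pred = np.where(v < t, below_label, not below_label)
                best = max(best, np.mean(pred == y))
    return best


class TestTwoCutTree:
    def test_single_axis_separable_reaches_full_accuracy(self, rng):
        conn = np.r_[rng.uniform(0.0, 0.35, 10), rng.uniform(0.45, 1.0, 10)]
        ieeg = rng.uniform(0, 1, 20)
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        tree = fit_two_cut_tree(np.c_[conn, ieeg], y)
        assert tree.training_accuracy == 1.0

    def test_corner_layout_needs_both_cuts(self):
        # seizure-free only in the low-low corner; no single cut separates
        pts = np.array([[0.1, 0.1], [0.9, 0.1], [0.1, 0.9], [0.9, 0.9], [0.15, 0.12], [0.85, 0.88]])
        y = np.array([True, False, False, False, True, False])
        assert _single_cut_best_accuracy(pts, y) < 1.0
        tree = fit_two_cut_tree(pts, y)
        assert tree.training_accuracy == 1.0

    def test_accuracy_consistent_with_stored_thresholds(self, rng):
        pts = rng.random((20, 2))
        y = rng.random(20) < 0.5
        if y.sum() < 2 or (~y).sum() < 2:
            y[:2], y[2:4] = True, False
        tree = fit_two_cut_tree(pts, y)
        rescored = np.mean(tree.predict([tuple(p) for p in pts]) == y)
        assert rescored == pytest.approx(tree.training_accuracy)

    def test_dominates_single_cut(self, rng):
        for _ in range(20):
            pts = rng.random((12, 2))
            y = np.r_[np.ones(6, bool), np.zeros(6, bool)]
            rng.shuffle(y)
            tree = fit_two_cut_tree(pts, y)
            assert tree.training_accuracy >= _single_cut_best_accuracy(pts, y) - 1e-12

    def test_loocv_minimal_cohort_runs(self):
        acc, sens, spec = loocv_tree(
            [(0.1, 0.1), (0.9, 0.9), (0.2, 0.2)], [True, False, True]
        )
        assert 0.0 <= acc <= 1.0

    def test_loocv_permuted_labels_near_chance(self, rng):
        pts = rng.random((24, 2))
        y = np.r_[np.ones(12, bool), np.zeros(12, bool)]
        accs = []
        for _ in range(20):
            rng.shuffle(y)
            accs.append(loocv_tree(pts, y)[0])
        assert 0.2 < np.mean(accs) < 0.7  # binomial noise around chance


class TestRankRegions:
    def test_descending_with_lexicographic_ties(self):
        assert rank_regions_for_implantation({"A": 2.0, "B": 1.0}) == ["A", "B"]
        assert rank_regions_for_implantation({"b": 1.0, "a": 1.0, "c": 2.0}) == [
            "c",
            "a",
            "b",
        ]

    def test_top_n_overflow_returns_all(self):
        assert rank_regions_for_implantation({"A": 1.0}, top_n=5) == ["A"]
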