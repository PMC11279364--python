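import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metsdx import accuracy as acc
from metsdx.accuracy import (
    AccuracyReport, ConfusionCounts, accuracy_measures, auc,
    bootstrap_youden_ci, clopper_pearson, compare_auc_paired_bootstrap,
    confusion_at, empirical_roc, evaluate_marker, optimal_cutoff,
)
from metsdx.markers import HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE
from metsdx.synthdata import BinormalSpec, generate_binormal_scores

SCORES = np.array([3.0, 5.0, 1.0, 4.0])
LABELS = np.array([True, True, False, False])


def brute_force_auc(scores, labels, orientation=HIGHER_IS_POSITIVE):
    """All-pairs Mann-Whitney concordance with half credit for ties."""
    scores = np.asarray(scores, float)
    pos, neg = scores[np.asarray(labels, bool)], scores[~np.asarray(labels, bool)]
    if orientation == HIGHER_IS_POSITIVE:
        wins = np.sum(pos[:, None] > neg[None, :])
    else:
        wins = np.sum(pos[:, None] < neg[None, :])
    ties = np.sum(pos[:, None] == neg[None, :])
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def brute_force_cutoff(scores, labels, orientation=HIGHER_IS_POSITIVE):
    """Exhaustive Youden maximization with the documented tie-break."""
    best = None
    for t in np.unique(scores):
        c = confusion_at(scores, labels, t, orientation)
        yi = c.tp / c.n_pos + c.tn / c.n_neg - 1.0
        tie = -t if orientation == HIGHER_IS_POSITIVE else t
        key = (round(yi, 12), tie)
        if best is None or key > best[0]:
            best = (key, float(t), yi)
    return best[1], best[2]


class TestEmpiricalRoc:
    def test_hand_enumerated_points(self):
        roc = empirical_roc(SCORES, LABELS)
        by_threshold = dict(zip(roc.thresholds, zip(roc.se, roc.sp)))
        assert by_threshold[3.0] == (1.0, 0.5)
        assert by_threshold[5.0] == (0.5, 1.0)

    def test_endpoints_present(self):
        roc = empirical_roc(SCORES, LABELS)
        points = set(zip(roc.se, roc.sp))
        assert (1.0, 0.0) in points and (0.0, 1.0) in points

    def test_perfect_separation_reaches_corner(self):
        roc = empirical_roc([1, 2, 8, 9], [0, 0, 1, 1])
        assert (1.0, 1.0) in set(zip(roc.se, roc.sp))

    def test_lower_orientation_is_negated_higher(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        hi = empirical_roc(-scores, labels, HIGHER_IS_POSITIVE)
        lo = empirical_roc(scores, labels, LOWER_IS_POSITIVE)
        assert auc(hi) == pytest.approx(auc(lo), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([1, 2, 3], [True, True, True])

    def test_monotone_curve(self):
        rng = np.random.default_rng(11)
        scores = rng.integers(0, 6, 80).astype(float)
        labels = rng.random(80) < 0.4
        labels[:2] = [True, False]
        roc = empirical_roc(scores, labels)
        # tightening the threshold: se falls, sp rises
        assert np.all(np.diff(roc.se) <= 1e-12)
        assert np.all(np.diff(roc.sp) >= -1e-12)


class TestAuc:
    def test_example(self):
        assert auc(empirical_roc(SCORES, LABELS)) == pytest.approx(0.75)

    def test_perfect(self):
        assert auc(empirical_roc([1, 2, 8, 9], [0, 0, 1, 1])) == 1.0

    def test_all_ties_half(self):
        assert auc(empirical_roc([2.0] * 10, [0, 1] * 5)) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(4, 120))
            scores = rng.integers(0, 10, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            for orientation in (HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE):
                got = auc(empirical_roc(scores, labels, orientation))
                assert got == pytest.approx(
                    brute_force_auc(scores, labels, orientation), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.5
        labels[:2] = [True, False]
        a1 = auc(empirical_roc(scores, labels))
        a2 = auc(empirical_roc(np.exp(scores), labels))
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestOptimalCutoff:
    def test_tie_broken_to_smallest_threshold(self):
        cutoff, se, sp = optimal_cutoff(empirical_roc(SCORES, LABELS))
        assert cutoff == 3.0 and (se, sp) == (1.0, 0.5)

    def test_perfect_separation(self):
        cutoff, se, sp = optimal_cutoff(empirical_roc([1, 2, 8, 9], [0, 0, 1, 1]))
        assert cutoff == 8.0 and se == 1.0 and sp == 1.0

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(5, 100))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            for orientation in (HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE):
                roc = empirical_roc(scores, labels, orientation)
                cutoff, se, sp = optimal_cutoff(roc)
                expect_cut, expect_yi = brute_force_cutoff(scores, labels, orientation)
                assert cutoff == expect_cut
                assert se + sp - 1 == pytest.approx(expect_yi, abs=1e-12)


class TestConfusion:
    def test_enumerated(self):
        c = confusion_at(SCORES, LABELS, 3.0, HIGHER_IS_POSITIVE)
        assert (c.tp, c.fn, c.tn, c.fp) == (2, 0, 1, 1)

    def test_threshold_below_min(self):
        c = confusion_at(SCORES, LABELS, -10.0)
        assert c.fp == 2 and c.fn == 0

    def test_threshold_above_max(self):
        c = confusion_at(SCORES, LABELS, 10.0)
        assert c.tp == 0 and c.tn == 2

    def test_class_totals(self):
        c = confusion_at(SCORES, LABELS, 4.0)
        assert c.n_pos == 2 and c.n_neg == 2


class TestAccuracyMeasures:
    def test_printed_row_identities(self):
        # 2x2 table reproducing a published row to 1/2 decimals
        report = accuracy_measures(ConfusionCounts(tp=448, fn=58, tn=867, fp=349))
        assert round(report.se, 1) == 88.5
        assert round(report.sp, 1) == 71.3
        assert round(report.ppv, 1) == 56.2
        assert round(report.npv, 1) == 93.7
        assert round(report.lrp, 2) == 3.08
        assert round(report.lrn, 2) == 0.16
        assert round(report.yi, 1) == 59.8

    def test_perfect(self):
        report = accuracy_measures(ConfusionCounts(tp=30, fn=0, tn=70, fp=0))
        assert (report.se, report.sp, report.ppv, report.npv, report.yi) == (
            100.0, 100.0, 100.0, 100.0, 100.0)
        assert math.isinf(report.lrp)

    def test_uninformative(self):
        report = accuracy_measures(ConfusionCounts(tp=25, fn=25, tn=25, fp=25))
        assert report.se == report.sp == 50.0
        assert report.lrp == pytest.approx(1.0) and report.lrn == pytest.approx(1.0)
        assert report.yi == pytest.approx(0.0)

    def test_undefined_ppv_is_nan_not_error(self):
        report = accuracy_measures(ConfusionCounts(tp=0, fn=10, tn=10, fp=0))
        assert math.isnan(report.ppv)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            accuracy_measures(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))


@given(tp=st.integers(0, 200), fn=st.integers(0, 200),
       tn=st.integers(0, 200), fp=st.integers(0, 200))
@settings(max_examples=150, deadline=None)
def test_measure_identities(tp, fn, tn, fp):
    if tp + fn == 0 or tn + fp == 0:
        return
    r = accuracy_measures(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))
    assert r.yi == pytest.approx(r.se + r.sp - 100.0, abs=1e-9)
    # percent-scale LR identities at full precision
    if r.sp < 100.0:
        assert r.lrp * (100.0 - r.sp) == pytest.approx(r.se, abs=1e-9)
    if r.sp > 0.0:
        assert r.lrn * r.sp == pytest.approx(100.0 - r.se, abs=1e-9)


class TestClopperPearson:
    def test_boundaries(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_spot_value(self):
        lo, hi = clopper_pearson(8, 10)
        assert lo == pytest.approx(0.4439, abs=5e-4)
        assert hi == pytest.approx(0.9748, abs=5e-4)

    def test_matches_binomial_tail_inversion(self):
        # independent oracle: root-find on the exact binomial tails
        from scipy.optimize import brentq

        for k, n in [(3, 12), (8, 10), (1, 30), (17, 40)]:
            lo, hi = clopper_pearson(k, n)
            # lower limit solves P(X >= k | p) = alpha/2,
            # upper limit solves P(X <= k | p) = alpha/2
            expect_lo = brentq(lambda p: (1 - stats.binom.cdf(k - 1, n, p)) - 0.025,
                               1e-12, 1 - 1e-12, xtol=1e-12)
            expect_hi = brentq(lambda p: stats.binom.cdf(k, n, p) - 0.025,
                               1e-12, 1 - 1e-12, xtol=1e-12)
            assert lo == pytest.approx(expect_lo, abs=1e-9)
            assert hi == pytest.approx(expect_hi, abs=1e-9)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


class TestBootstrapYouden:
    def test_deterministic(self):
        s, l = generate_binormal_scores(BinormalSpec(80, 80, 1.0, seed=5))
        ci1 = bootstrap_youden_ci(s, l, B=300, seed=9)
        ci2 = bootstrap_youden_ci(s, l, B=300, seed=9)
        assert ci1 == ci2

    def test_constant_scores_degenerate(self):
        ci = bootstrap_youden_ci([2.0] * 20, [0, 1] * 10, B=200, seed=1)
        assert ci == (0.0, 0.0)

    def test_seed_required(self):
        with pytest.raises(ValueError):
            bootstrap_youden_ci([1, 2, 3, 4], [0, 0, 1, 1], B=200)

    def test_small_B_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_youden_ci([1, 2, 3, 4], [0, 0, 1, 1], B=50, seed=1)

    def test_interval_brackets_point_estimate_roughly(self):
        s, l = generate_binormal_scores(BinormalSpec(400, 400, 1.5, seed=2))
        roc = empirical_roc(s, l)
        _, se, sp = optimal_cutoff(roc)
        yi = 100 * (se + sp - 1)
        lo, hi = bootstrap_youden_ci(s, l, B=500, seed=3)
        assert lo < yi < hi


class TestPairedAucComparison:
    def test_identical_markers(self):
        s, l = generate_binormal_scores(BinormalSpec(100, 100, 1.0, seed=6))
        result = compare_auc_paired_bootstrap(s, s, l, B=200, seed=4)
        assert result.delta_auc == 0.0 and result.p_value == 1.0

    def test_swap_negates_delta_preserves_p(self):
        rng = np.random.default_rng(8)
        l = np.repeat([False, True], 150)
        a = rng.normal(size=300) + 1.0 * l
        b = rng.normal(size=300) + 0.4 * l
        r1 = compare_auc_paired_bootstrap(a, b, l, B=400, seed=12)
        r2 = compare_auc_paired_bootstrap(b, a, l, B=400, seed=12)
        assert r1.delta_auc == pytest.approx(-r2.delta_auc)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        l = np.repeat([False, True], 60)
        a = rng.normal(size=120) + l
        b = rng.normal(size=120)
        r1 = compare_auc_paired_bootstrap(a, b, l, B=300, seed=2)
        r2 = compare_auc_paired_bootstrap(a, b, l, B=300, seed=2)
        assert (r1.delta_auc, r1.p_value) == (r2.delta_auc, r2.p_value)

    def test_mixed_orientations(self):
        s, l = generate_binormal_scores(BinormalSpec(120, 120, 1.2, seed=10))
        result = compare_auc_paired_bootstrap(
            s, -s, l, orientations=(HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE),
            B=200, seed=3)
        assert result.delta_auc == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == 1.0


class TestEvaluateMarker:
    def test_perfect_marker(self):
        report = evaluate_marker([1, 2, 8, 9], [0, 0, 1, 1], B=200, seed=1)
        assert report.auc == 1.0 and report.yi == 100.0
        assert report.se_ci[1] == 100.0

    def test_composition_consistency(self):
        s, l = generate_binormal_scores(BinormalSpec(300, 300, 1.2, seed=13))
        report = evaluate_marker(s, l, B=300, seed=5)
        assert report.yi == pytest.approx(report.se + report.sp - 100.0, abs=1e-9)
        c = confusion_at(s, l, report.cutoff)
        assert report.se == pytest.approx(100.0 * c.tp / c.n_pos)
        lo, hi = report.se_ci
        expect = tuple(100 * x for x in clopper_pearson(int(c.tp), int(c.n_pos)))
        assert (lo, hi) == pytest.approx(expect)
        assert report.auc_ci[0] < report.auc < report.auc_ci[1]

    def test_no_bootstrap_when_B_zero(self):
        s, l = generate_binormal_scores(BinormalSpec(50, 50, 1.0, seed=14))
        report = evaluate_marker(s, l, B=0)
        assert report.yi_ci is None and report.se_ci is not None

    def test_lower_orientation_cutoff_direction(self):
        s, l = generate_binormal_scores(BinormalSpec(200, 200, 1.5, seed=15))
        hi_rep = evaluate_marker(s, l, HIGHER_IS_POSITIVE, B=0)
        lo_rep = evaluate_marker(-s, l, LOWER_IS_POSITIVE, B=0)
        assert lo_rep.auc == pytest.approx(hi_rep.auc, abs=1e-12)
        assert lo_rep.cutoff == pytest.approx(-hi_rep.cutoff)
        assert lo_rep.yi == pytest.approx(hi_rep.yi, abs=1e-9)
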