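"""2x2 statistics, odds ratios, tests and ROC/AUC machinery, each checked
against an independent oracle (hand arithmetic, exhaustive enumeration, or
brute-force pairwise counting)."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from qsirs.accuracy import (
    ContingencyTable,
    choose_test,
    delong_compare,
    diagnostic_metrics,
    fisher_exact,
    make_contingency,
    mann_whitney_auc,
    odds_ratio_woolf,
    pearson_chi2,
    roc_curve,
    truncate_percent,
)

# the three published score-vs-death tables used as realistic inputs
QSOFA_CT = ContingencyTable(4, 9, 7, 98)
SIRS_CT = ContingencyTable(9, 38, 2, 69)
QSIRS_CT = ContingencyTable(10, 49, 1, 58)


def brute_force_auc(scores, deaths):
    """Independent O(m*n) pairwise count: P(dead > alive) + 0.5 P(tie)."""
    dead = [s for s, d in zip(scores, deaths) if d]
    alive = [s for s, d in zip(scores, deaths) if not d]
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in dead for y in alive)
    return wins / (len(dead) * len(alive))


def enumerate_fisher_p(ct: ContingencyTable) -> float:
    """Exhaustive two-sided Fisher p: sum hypergeometric probabilities of
    every table with the observed margins that is no more probable."""
    r1, c1, total = ct.positives, ct.deaths, ct.total
    pmf = stats.hypergeom(total, c1, r1).pmf
    p_obs = pmf(ct.tp)
    lo = max(0, r1 + c1 - total)
    hi = min(r1, c1)
    return float(
        sum(pmf(a) for a in range(lo, hi + 1) if pmf(a) <= p_obs * (1 + 1e-7))
    )


class TestContingency:
    def test_reconstructed_study_table(self):
        pos = [True] * 13 + [False] * 105
        dead = [True] * 4 + [False] * 9 + [True] * 7 + [False] * 98
        ct = make_contingency(pos, dead)
        assert ct == QSOFA_CT
        assert ct.total == 118 and ct.deaths == 11

    def test_degenerate_all_positive_all_dead(self):
        assert make_contingency([True] * 5, [True] * 5) == ContingencyTable(5, 0, 0, 0)

    def test_hand_countable_alternating(self):
        ct = make_contingency([True, False, True, False], [True, False, False, True])
        assert ct == ContingencyTable(1, 1, 1, 1)

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            make_contingency([True], [True, False])
        with pytest.raises(ValueError, match="empty"):
            make_contingency([], [])

    def test_negative_or_fractional_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 5)


class TestDiagnosticMetrics:
    @pytest.mark.parametrize(
        "ct, sens, spec, ppv, npv",
        [
            (QSOFA_CT, "36.3", "91.5", "30.7", "93.3"),
            (SIRS_CT, "81.8", "64.4", "19.1", "97.1"),
            (QSIRS_CT, "90.9", "54.2", "16.9", "98.3"),
        ],
    )
    def test_published_rows_reproduced_by_truncation(self, ct, sens, spec, ppv, npv):
        m = diagnostic_metrics(ct)
        assert m.sensitivity.percent() == sens
        assert m.specificity.percent() == spec
        assert m.ppv.percent() == ppv
        assert m.npv.percent() == npv

    def test_perfect_classifier(self):
        m = diagnostic_metrics(ContingencyTable(5, 0, 0, 5))
        for est in (m.sensitivity, m.specificity, m.ppv, m.npv):
            assert est.value == 1.0 and est.percent() == "100.0"

    def test_zero_denominator_flagged_undefined_not_zero(self):
        m = diagnostic_metrics(ContingencyTable(0, 5, 0, 5))  # no deaths
        assert m.sensitivity.value is None
        assert "zero denominator" in m.sensitivity.reason
        assert m.sensitivity.percent() == "undefined"
        assert m.specificity.value == 0.5

    def test_clopper_pearson_ci_contains_point(self):
        m = diagnostic_metrics(QSIRS_CT)
        for est in (m.sensitivity, m.specificity, m.ppv, m.npv):
            lo, hi = est.ci
            assert lo <= est.value <= hi

    def test_complementarity_fnr_and_fpr(self):
        for ct in (QSOFA_CT, SIRS_CT, QSIRS_CT, ContingencyTable(3, 1, 4, 2)):
            m = diagnostic_metrics(ct, with_ci=False)
            assert m.sensitivity.value + ct.fn / ct.deaths == pytest.approx(1.0)
            assert m.specificity.value + ct.fp / ct.survivors == pytest.approx(1.0)


class TestTruncation:
    @pytest.mark.parametrize(
        "value, rendered",
        [
            (4 / 11, "36.3"),     # 36.36 truncates, does not round, to 36.3
            (69 / 71, "97.1"),    # 97.18 -> 97.1
            (98 / 107, "91.5"),   # 91.58 -> 91.5 (rounding would give 91.6)
            (0.5, "50.0"),
            (1.0, "100.0"),
            (0.0, "0.0"),
        ],
    )
    def test_truncates_to_one_decimal(self, value, rendered):
        assert truncate_percent(value) == rendered

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            truncate_percent(1.2)


class TestOddsRatio:
    def test_published_qsofa_point_and_ci(self):
        r = odds_ratio_woolf(QSOFA_CT)
        assert r.odds_ratio == pytest.approx(6.222, abs=0.001)
        assert r.ci_low == pytest.approx(1.53, abs=0.01)
        assert r.ci_high == pytest.approx(25.4, abs=0.1)
        assert r.method == "woolf"

    def test_symmetric_table_gives_unit_or(self):
        assert odds_ratio_woolf(ContingencyTable(1, 1, 1, 1)).odds_ratio == 1.0

    def test_against_independent_log_or_arithmetic(self):
        # oracle: the Woolf formula evaluated step by step on (10,49,1,58)
        a, b, c, d = 10, 49, 1, 58
        log_or = math.log(a) + math.log(d) - math.log(b) - math.log(c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = stats.norm.ppf(0.975)
        r = odds_ratio_woolf(QSIRS_CT)
        assert r.odds_ratio == pytest.approx(math.exp(log_or), rel=1e-12)
        assert r.ci_low == pytest.approx(math.exp(log_or - z * se), rel=1e-12)
        assert r.ci_high == pytest.approx(math.exp(log_or + z * se), rel=1e-12)

    def test_zero_cell_errors_with_haldane_opt_in(self):
        ct = ContingencyTable(0, 5, 5, 5)
        with pytest.raises(ValueError, match="haldane"):
            odds_ratio_woolf(ct)
        r = odds_ratio_woolf(ct, haldane=True)
        assert r.method == "woolf_haldane"
        assert r.odds_ratio == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))

    def test_ci_brackets_point_estimate(self):
        for ct in (QSOFA_CT, SIRS_CT, QSIRS_CT):
            r = odds_ratio_woolf(ct)
            assert r.ci_low <= r.odds_ratio <= r.ci_high


class TestChi2AndFisher:
    def test_exact_independence_gives_zero_statistic(self):
        r = pearson_chi2(ContingencyTable(25, 25, 25, 25))
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_against_hand_computed_expected_counts(self):
        # oracle: expected counts from margins, summed by hand for (9,38,2,69)
        ct = SIRS_CT
        expected = [
            47 * 11 / 118, 47 * 107 / 118, 71 * 11 / 118, 71 * 107 / 118,
        ]
        observed = [9, 38, 2, 69]
        oracle_stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        r = pearson_chi2(ct)
        assert r.statistic == pytest.approx(oracle_stat, rel=1e-12)
        assert r.statistic == pytest.approx(8.9236, abs=5e-4)
        assert r.p_value == pytest.approx(stats.chi2.sf(oracle_stat, 1), rel=1e-12)

    def test_expected_min_flags_sparse_table(self):
        r = pearson_chi2(QSOFA_CT)
        assert r.expected_min == pytest.approx(13 * 11 / 118)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2(ContingencyTable(0, 0, 5, 5))

    def test_fisher_small_table_by_enumeration(self):
        # margins (2,2)/(2,2): three attainable tables with probs 1/6, 4/6, 1/6;
        # observing the 1/6 corner gives two-sided p = 2/6
        r = fisher_exact(ContingencyTable(2, 0, 0, 2))
        assert r.p_value == pytest.approx(1 / 3)
        assert r.statistic is None

    def test_fisher_label_swap_symmetry(self):
        p1 = fisher_exact(ContingencyTable(0, 5, 5, 0)).p_value
        p2 = fisher_exact(ContingencyTable(5, 0, 0, 5)).p_value
        assert p1 == pytest.approx(p2)

    def test_fisher_significant_on_sparse_published_table(self):
        assert fisher_exact(QSOFA_CT).p_value <= 0.05

    @pytest.mark.parametrize("cells", [(2, 3, 4, 5), (1, 9, 3, 7), (6, 1, 2, 11)])
    def test_fisher_matches_exhaustive_enumeration(self, cells):
        ct = ContingencyTable(*cells)
        assert fisher_exact(ct).p_value == pytest.approx(enumerate_fisher_p(ct), rel=1e-9)

    def test_choose_test_cochran_rule(self):
        assert choose_test(QSOFA_CT) == "fisher_exact"       # expected_min 1.21
        assert choose_test(ContingencyTable(25, 25, 25, 25)) == "pearson_chi2"
        # (10,49,1,58): all expected counts are 5.5 or 53.5 -> chi-square
        assert float(QSIRS_CT.expected_counts().min()) == pytest.approx(5.5)
        assert choose_test(QSIRS_CT) == "pearson_chi2"


class TestRoc:
    def test_perfect_separation(self):
        scores = [0, 1, 2, 3, 3, 3]
        deaths = [False, False, False, True, True, True]
        r = roc_curve(scores, deaths)
        assert r.auc == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_curve([2] * 8, [True] * 3 + [False] * 5).auc == 0.5

    def test_auc_equals_brute_force_pairwise_count_with_ties(self):
        scores = [0, 1, 1, 2, 3, 3, 0, 1, 2, 2, 3, 4]
        deaths = [True] * 6 + [False] * 6
        r = roc_curve(scores, deaths)
        assert r.auc == pytest.approx(brute_force_auc(scores, deaths), rel=1e-12)

    def test_curve_anchored_and_monotone(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 5, size=40).astype(float)
        deaths = rng.random(40) < 0.3
        r = roc_curve(scores, deaths)
        pts = [(fp, se) for _, se, fp in r.operating_points]
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        assert all(a <= b for a, b in zip(pts, pts[1:]))

    def test_auc_equals_trapezoid_over_operating_points(self):
        rng = np.random.default_rng(7)
        scores = rng.integers(0, 6, size=60).astype(float)
        deaths = rng.random(60) < 0.25
        r = roc_curve(scores, deaths)
        fpr = np.array([p[2] for p in r.operating_points])
        tpr = np.array([p[1] for p in r.operating_points])
        assert r.auc == pytest.approx(float(np.trapezoid(tpr, fpr)), rel=1e-12)

    def test_delong_ci_contains_auc_and_variance_nonnegative(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=50) + rng.random(50)
        deaths = rng.random(50) < 0.3
        r = roc_curve(scores, deaths)
        assert r.variance >= 0
        assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="death and one survivor"):
            roc_curve([1.0, 2.0], [True, True])

    @given(st.data())
    def test_auc_invariant_under_strictly_monotone_transform(self, data):
        n = data.draw(st.integers(6, 25))
        scores = data.draw(
            st.lists(st.integers(0, 6), min_size=n, max_size=n)
        )
        deaths = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda d: any(d) and not all(d)
            )
        )
        base = mann_whitney_auc([float(s) for s in scores], deaths)
        transformed = mann_whitney_auc([math.exp(0.5 * s) for s in scores], deaths)
        assert transformed == pytest.approx(base, rel=1e-12)

    @given(st.data())
    def test_outcome_label_swap_maps_auc_to_complement(self, data):
        n = data.draw(st.integers(6, 25))
        scores = [float(s) for s in data.draw(
            st.lists(st.integers(0, 6), min_size=n, max_size=n))]
        deaths = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda d: any(d) and not all(d)
            )
        )
        auc = mann_whitney_auc(scores, deaths)
        flipped = mann_whitney_auc(scores, [not d for d in deaths])
        assert flipped == pytest.approx(1.0 - auc, rel=1e-12)

    @given(st.data())
    def test_binary_score_auc_equals_mean_of_sens_and_spec(self, data):
        n = data.draw(st.integers(6, 30))
        positives = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        deaths = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda d: any(d) and not all(d)
            )
        )
        auc = mann_whitney_auc([float(p) for p in positives], deaths)
        ct = make_contingency(positives, deaths)
        m = diagnostic_metrics(ct, with_ci=False)
        sens = m.sensitivity.value
        spec = m.specificity.value
        assert auc == pytest.approx((sens + spec) / 2, rel=1e-12)


class TestDelongCompare:
    def test_self_comparison_gives_zero_difference_p_one(self):
        scores = [0.0, 1.0, 2.0, 3.0, 1.0, 2.0]
        deaths = [True, True, False, True, False, False]
        r = delong_compare(scores, scores, deaths)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_both_scores_constant_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            delong_compare([1.0] * 6, [2.0] * 6, [True, False] * 3)

    def test_directionality_of_z(self):
        rng = np.random.default_rng(5)
        deaths = np.array([True] * 5 + [False] * 10)
        a = np.concatenate([rng.normal(2, 1, 5), rng.normal(0, 1, 10)])
        b = a.copy()
        b[7] = a[deaths].max() + 5.0  # one survivor now outscores every death
        r = delong_compare(a, b, deaths)
        auc_a = mann_whitney_auc(a, deaths)
        auc_b = mann_whitney_auc(b, deaths)
        assert auc_b < auc_a
        assert r.statistic > 0
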