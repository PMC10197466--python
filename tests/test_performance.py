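"""Contingency metrics, exact confidence intervals, and Fisher's exact test."""

import math
from math import comb

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from mgscreen.errors import IncompleteResultsError, InvalidInputError
from mgscreen.performance import (
    ContingencyTable,
    build_contingency,
    clopper_pearson,
    combo_sensitivity_table,
    fisher_exact,
    metrics,
    percent,
    threshold_sweep,
)
from mgscreen.screening import AssayResults


class TestBuildContingency:
    def test_perfect_agreement(self):
        t = build_contingency([True, False], [True, False])
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 1)

    def test_false_positive(self):
        assert build_contingency([True], [False]).fp == 1

    def test_counts_from_case_control_flags(self):
        # 33 of 54 cases and 2 of 120 controls flagged
        pred = [True] * 33 + [False] * 21 + [True] * 2 + [False] * 118
        truth = [True] * 54 + [False] * 120
        t = build_contingency(pred, truth)
        assert (t.tp, t.fn, t.fp, t.tn) == (33, 21, 2, 118)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            build_contingency([True], [True, False])

    def test_negative_count_rejected(self):
        with pytest.raises(InvalidInputError):
            ContingencyTable(-1, 0, 0, 1)


class TestMetrics:
    def test_screening_rule_metrics(self):
        m = metrics(ContingencyTable(tp=33, fn=21, fp=2, tn=118))
        assert m["ppv"].estimate == pytest.approx(33 / 35)
        assert percent(m["ppv"].estimate) == 94
        assert percent(m["npv"].estimate) == 85
        assert percent(m["sens"].estimate) == 61
        assert percent(m["spec"].estimate) == 98

    def test_perfect_ppv_exact_interval(self):
        m = metrics(ContingencyTable(tp=19, fn=35, fp=0, tn=120))
        assert m["ppv"].estimate == 1.0
        assert percent(m["ppv"].ci_low) == 82
        assert m["ppv"].ci_high == 1.0

    def test_zero_denominator_is_marked_undefined(self):
        m = metrics(ContingencyTable(tp=0, fp=0, fn=5, tn=5))
        assert not m["ppv"].defined
        assert math.isnan(m["ppv"].estimate)
        assert m["sens"].defined  # other metrics unaffected

    def test_predictive_values_satisfy_bayes(self):
        """PPV/NPV via Bayes from sens, spec and sample prevalence match the ratios."""
        t = ContingencyTable(tp=41, fn=13, fp=27, tn=93)
        m = metrics(t)
        prev = (t.tp + t.fn) / t.n
        sens, spec = m["sens"].estimate, m["spec"].estimate
        ppv = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
        npv = spec * (1 - prev) / (spec * (1 - prev) + (1 - sens) * prev)
        assert m["ppv"].estimate == pytest.approx(ppv, abs=1e-12)
        assert m["npv"].estimate == pytest.approx(npv, abs=1e-12)

    @pytest.mark.parametrize("n", [10, 100, 1000])
    def test_ci_width_shrinks_with_n(self, n):
        low, high = clopper_pearson(n // 2, n)
        if n > 10:
            prev_low, prev_high = clopper_pearson(n // 20, n // 10)
        else:
            return
        assert (high - low) < (prev_high - prev_low)


def binomial_tail_ge(k: int, n: int, p: float) -> float:
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def binomial_tail_le(k: int, n: int, p: float) -> float:
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1))


def cp_oracle(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson bounds by bisection on hand-summed binomial tails."""
    alpha = 1 - level

    def solve(f, target):
        lo, hi = 0.0, 1.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    low = 0.0 if k == 0 else solve(lambda p: binomial_tail_ge(k, n, p), alpha / 2)
    high = 1.0 if k == n else 1.0 - solve(
        lambda p: binomial_tail_le(k, n, 1.0 - p), alpha / 2
    )
    return low, high


class TestClopperPearson:
    @pytest.mark.parametrize("k,n", [(0, 10), (3, 10), (19, 19), (50, 60), (1, 2)])
    def test_matches_tail_sum_oracle(self, k, n):
        low, high = clopper_pearson(k, n)
        olow, ohigh = cp_oracle(k, n)
        assert low == pytest.approx(olow, abs=1e-9)
        assert high == pytest.approx(ohigh, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            clopper_pearson(5, 0)
        with pytest.raises(InvalidInputError):
            clopper_pearson(7, 5)


class TestFisherExact:
    def test_tea_tasting_table(self):
        # full enumeration: support pmf (1,16,36,16,1)/70, observed 16/70 -> 34/70
        assert fisher_exact(ContingencyTable(3, 1, 1, 3)) == pytest.approx(34 / 70)

    @pytest.mark.parametrize("a,b", [(2, 3), (5, 5), (1, 7)])
    def test_identical_rows_give_p_one(self, a, b):
        assert fisher_exact(ContingencyTable(a, b, a, b)) == pytest.approx(1.0)

    def test_screening_rule_association_is_strong(self):
        p = fisher_exact(ContingencyTable(tp=33, fn=21, fp=2, tn=118))
        assert 0 < p < 0.001

    def test_zero_margin_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact(ContingencyTable(0, 0, 3, 4)) == 1.0

    @given(
        st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
    )
    def test_matches_scipy_reference(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        expected = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert fisher_exact(t) == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestThresholdSweep:
    def test_reproduces_screening_rule_rows(self):
        cases = [3] * 33 + [2] * 10 + [1] * 11
        controls = [3] * 2 + [2] * 13 + [1] * 37 + [0] * 68
        rows = {r.threshold: r for r in threshold_sweep(cases, controls)}
        assert (rows[3].table.tp, rows[3].table.fp) == (33, 2)
        assert percent(rows[3].metrics["sens"].estimate) == 61
        assert percent(rows[3].metrics["spec"].estimate) == 98
        assert rows[1].metrics["sens"].estimate == 1.0  # every case has >=1
        assert rows[1].control_fraction_zero == pytest.approx(68 / 120)

    def test_flagged_sets_nest_with_threshold(self):
        rng = np.random.default_rng(7)
        cases = rng.integers(0, 7, 40).tolist()
        controls = rng.integers(0, 7, 80).tolist()
        rows = threshold_sweep(cases, controls, thresholds=range(1, 7))
        for lo, hi in zip(rows, rows[1:]):
            assert hi.table.tp <= lo.table.tp
            assert hi.table.fp <= lo.table.fp

    def test_all_zero_counts(self):
        rows = threshold_sweep([0, 0], [0, 0, 0], thresholds=(1,))
        assert rows[0].metrics["sens"].estimate == 0.0
        assert rows[0].metrics["spec"].estimate == 1.0

    def test_out_of_range_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            threshold_sweep([7], [0])


class TestComboSensitivityTable:
    def make_results(self, n_pos_spep, n_total):
        out = []
        for i in range(n_total):
            out.append(
                AssayResults(
                    spep_positive=i < n_pos_spep,
                    sife_positive=True,
                    uife_positive=False,
                    flc_ratio_abnormal=False,
                )
            )
        return out

    def test_single_assay_fraction(self):
        table = combo_sensitivity_table(self.make_results(43, 54), [("SPEP",)])
        m = table[frozenset({"SPEP"})]
        assert m.estimate == pytest.approx(43 / 54)
        assert percent(m.estimate) == 80

    def test_undetectable_patient_caps_sensitivity(self):
        results = self.make_results(0, 1) + [
            AssayResults(True, True, True, True) for _ in range(53)
        ]
        results[0] = AssayResults(False, False, False, False)  # non-secretory
        table = combo_sensitivity_table(results, [("SPEP", "SIFE", "UIFE", "SFLCA")])
        m = table[frozenset({"SPEP", "SIFE", "UIFE", "SFLCA"})]
        assert m.numerator == 53
        assert percent(m.estimate) == 98

    def test_empty_combo_zero_by_convention(self):
        table = combo_sensitivity_table(self.make_results(3, 5), [()])
        assert table[frozenset()].estimate == 0.0

    def test_incomplete_results_listed(self):
        results = [AssayResults(spep_positive=True)]
        with pytest.raises(IncompleteResultsError, match=r"\(0, UIFE\)"):
            combo_sensitivity_table(results, [("UIFE",)])


class TestPercent:
    @pytest.mark.parametrize(
        "p,expected", [(0.611, 61), (0.775, 78), (0.005, 1), (0.0, 0), (1.0, 100)]
    )
    def test_rounds_ties_away_from_zero(self, p, expected):
        assert percent(p) == expected
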