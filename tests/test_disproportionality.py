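"""Unit and property tests for the 2x2 disproportionality statistics."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from pvscreen import (Cohort, ContingencyTable, SignalStats, ThresholdConfig,
                      compute_stats, flag_signal, prr_with_chi2, ror_with_ci,
                      round_half_away, run_screen, term_pairs)
from pvscreen.disproportionality import UNMAPPED_SOC

from conftest import make_report


def printed_decimals(text: str) -> int:
    return len(text.split(".")[1]) if "." in text else 0


def assert_matches_printed(value: float, printed: str) -> None:
    """Agreement at the printed precision (trailing zeros dropped)."""
    nd = min(printed_decimals(printed), 2)
    assert round_half_away(value, nd) == pytest.approx(float(printed), abs=1e-12)


class TestRorPrr:
    @pytest.mark.parametrize("a,b,c,d,ror,lo,hi", [
        (9, 1514, 5, 5183, "6.16", "2.06", "18.41"),    # anaemia
        (30, 1493, 8, 5180, "13.01", "5.95", "28.44"),  # hypotension
        (9, 1514, 1, 5187, "30.83", "3.9", "243.58"),   # hepatic enzyme inc.
    ])
    def test_ror_reference_rows(self, a, b, c, d, ror, lo, hi):
        got = ror_with_ci(ContingencyTable(a, b, c, d))
        assert_matches_printed(got.ror, ror)
        assert_matches_printed(got.ci_low, lo)
        assert_matches_printed(got.ci_high, hi)

    @pytest.mark.parametrize("a,b,c,d,prr,chi2", [
        (9, 1514, 5, 5183, "6.13", "13.83"),
        (108, 1415, 83, 5105, "4.43", "128.4"),
        (30, 1493, 8, 5180, "12.77", "68.93"),
    ])
    def test_prr_reference_rows(self, a, b, c, d, prr, chi2):
        got = prr_with_chi2(ContingencyTable(a, b, c, d))
        assert_matches_printed(got.prr, prr)
        assert_matches_printed(got.chi2, chi2)

    def test_balanced_table_is_null(self):
        t = ContingencyTable(10, 10, 10, 10)
        ror = ror_with_ci(t)
        assert ror.ror == 1.0
        # CI symmetric about 1 in log space
        assert ror.ci_low * ror.ci_high == pytest.approx(1.0)
        prr = prr_with_chi2(t)
        assert prr.prr == 1.0
        assert prr.chi2 == 0.0

    def test_zero_cells_yield_explicit_undefined(self):
        assert ror_with_ci(ContingencyTable(5, 0, 3, 10)) == (None, None, None)
        assert ror_with_ci(ContingencyTable(5, 3, 0, 10)) == (None, None, None)
        # defined point estimate, undefined CI
        got = ror_with_ci(ContingencyTable(0, 3, 2, 10))
        assert got.ror == 0.0 and got.ci_low is None
        assert prr_with_chi2(ContingencyTable(5, 3, 0, 10)) == (None, None)

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    @given(a=st.integers(1, 500), b=st.integers(1, 5000),
           c=st.integers(1, 5000), d=st.integers(1, 50000))
    @settings(max_examples=200, deadline=None)
    def test_chi2_equals_brute_force_expected_counts(self, a, b, c, d):
        """Shortcut chi-square formula agrees with Σ(O−E)²/E to 1e-9."""
        t = ContingencyTable(a, b, c, d)
        got = prr_with_chi2(t).chi2
        n = t.n
        brute = 0.0
        for obs, row, col in [(a, a + b, a + c), (b, a + b, b + d),
                              (c, c + d, a + c), (d, c + d, b + d)]:
            exp = row * col / n
            brute += (obs - exp) ** 2 / exp
        assert got == pytest.approx(brute, abs=1e-9, rel=1e-9)

    def test_chi2_matches_scipy_uncorrected(self):
        t = ContingencyTable(108, 1415, 83, 5105)
        expected = chi2_contingency([[t.a, t.b], [t.c, t.d]],
                                    correction=False).statistic
        assert prr_with_chi2(t).chi2 == pytest.approx(expected, rel=1e-12)

    @given(a=st.integers(1, 400))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_a(self, a):
        """Holding b, c, d fixed, ROR and PRR strictly increase with a."""
        lo = ContingencyTable(a, 1500, 50, 5000)
        hi = ContingencyTable(a + 1, 1500, 50, 5000)
        assert ror_with_ci(hi).ror > ror_with_ci(lo).ror
        assert prr_with_chi2(hi).prr > prr_with_chi2(lo).prr

    def test_ror_close_to_prr_for_rare_events(self, pt_reference):
        """In the rare-event limit (a ≪ a+b, c ≪ c+d) the two measures
        nearly coincide on every reference row."""
        for row in pt_reference.itertuples():
            if row.a / (row.a + row.b) < 0.05:
                t = ContingencyTable(row.a, row.b, row.c, row.d)
                ror = ror_with_ci(t).ror
                prr = prr_with_chi2(t).prr
                assert abs(ror - prr) / prr < 0.05


class TestFlags:
    TH = ThresholdConfig()

    def _flag(self, a, b, c, d):
        return flag_signal(compute_stats("x", "PT", ContingencyTable(a, b, c, d)),
                           self.TH)

    def test_ror_only_signal(self):
        # general-disorders SOC row: CI low 1.08 > 1 but PRR 1.19 < 2
        s = self._flag(338, 1185, 971, 4217)
        assert s.ror_positive and not s.prr_positive and not s.positive_both

    def test_dual_algorithm_signal(self):
        # nervous-system SOC row: CI low 2, PRR 2.18, chi2 97.43
        s = self._flag(228, 1295, 356, 4832)
        assert s.ror_positive and s.prr_positive and s.positive_both

    def test_min_count_gate_dominates(self):
        s = self._flag(2, 10, 1, 5000)  # huge ROR but a < 3
        assert not s.ror_positive and not s.prr_positive

    def test_undefined_stats_never_positive(self):
        s = self._flag(5, 1500, 0, 5000)
        assert not s.ror_positive and not s.prr_positive


class TestTermPairs:
    MAP = {"Dizziness": "Nervous system disorders",
           "Somnolence": "Nervous system disorders",
           "Nausea": "Gastrointestinal disorders"}

    def test_distinct_count_semantics(self):
        reports = [make_report(caseid=1, events={"Dizziness", "Somnolence"})]
        pt_counts, pt_margin = term_pairs(reports, self.MAP, "PT")
        soc_counts, soc_margin = term_pairs(reports, self.MAP, "SOC")
        assert pt_counts == {"Dizziness": 1, "Somnolence": 1} and pt_margin == 2
        assert soc_counts == {"Nervous system disorders": 1} and soc_margin == 1

    def test_unmapped_pt_goes_to_sentinel(self):
        counts, _ = term_pairs([make_report(events={"Mystery event"})],
                               self.MAP, "SOC")
        assert counts == {UNMAPPED_SOC: 1}

    def test_order_invariance(self):
        reports = [make_report(caseid=i, events={"Dizziness"} if i % 2 else
                               {"Nausea", "Somnolence"}) for i in range(20)]
        forward = term_pairs(reports, self.MAP, "PT")
        backward = term_pairs(list(reversed(reports)), self.MAP, "PT")
        assert forward == backward

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            term_pairs([], self.MAP, "PT")


class TestRunScreen:
    def test_margins_shared_and_sorted(self):
        rng = np.random.default_rng(7)
        pts = list(TestTermPairs.MAP)
        target = [make_report(caseid=i,
                              events=set(rng.choice(pts, size=2, replace=False)))
                  for i in range(30)]
        comp = [make_report(caseid=100 + i, ps_drug="LISINOPRIL",
                            events={pts[int(rng.integers(3))]})
                for i in range(60)]
        res = run_screen(Cohort(target, comp), TestTermPairs.MAP)
        for level in ("SOC", "PT"):
            rows = [s for s in res if s.level == level]
            margins = {s.table.a + s.table.b for s in rows}
            comp_margins = {s.table.c + s.table.d for s in rows}
            assert len(margins) == 1 and len(comp_margins) == 1
            assert [(-s.table.a, s.term) for s in rows] == \
                sorted((-s.table.a, s.term) for s in rows)
        # SOC block precedes PT block
        assert [s.level for s in res] == sorted(
            (s.level for s in res), key={"SOC": 0, "PT": 1}.get)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            run_screen(Cohort([], [make_report()]), TestTermPairs.MAP)
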