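"""ROR estimation, 2x2 construction, ranking and frequency normalization."""

from __future__ import annotations

import math
from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.disproportionality import (
    ContingencyTable,
    build_contingency,
    compute_ror,
    normalized_frequency,
    rank_top,
    screen_stratum,
)

cells = st.integers(min_value=1, max_value=60)


class TestComputeRor:
    def test_proportional_table_is_null(self):
        est = compute_ror(ContingencyTable(10, 20, 30, 60))
        assert est.ror == pytest.approx(1.0)
        assert not est.is_signal

    def test_symmetric_table_ci(self):
        # closed-form: ROR=1, SE=sqrt(4/5), CI = exp(+-1.96*sqrt(0.8))
        est = compute_ror(ContingencyTable(5, 5, 5, 5))
        assert est.ror == pytest.approx(1.0)
        assert est.se_log == pytest.approx(math.sqrt(0.8))
        assert est.ci_low == pytest.approx(0.17324001182, rel=1e-9)
        assert est.ci_high == pytest.approx(5.77233855763, rel=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_reciprocal_symmetry(self, a, b, c, d):
        """Swapping the table rows inverts the odds ratio exactly."""
        fwd = compute_ror(ContingencyTable(a, b, c, d))
        rev = compute_ror(ContingencyTable(b, a, d, c))
        assert fwd.ror * rev.ror == pytest.approx(1.0, rel=1e-12)
        assert fwd.se_log == pytest.approx(rev.se_log, rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(a=st.integers(1, 40), b=cells, c=cells, d=cells)
    def test_monotone_in_a(self, a, b, c, d):
        """More target reports with the PT strictly raises ROR and its lower bound."""
        lo = compute_ror(ContingencyTable(a, b, c, d))
        hi = compute_ror(ContingencyTable(a + 1, b, c, d))
        assert hi.ror > lo.ror
        assert hi.ci_low > lo.ci_low

    def test_statsmodels_cross_check(self):
        """Independent log-OR implementation agrees on a spread of tables."""
        sm = pytest.importorskip("statsmodels.api")
        for table in [(5, 5, 5, 5), (369, 466, 3000, 96000), (2, 50, 7, 13),
                      (165, 670, 40, 99000)]:
            est = compute_ror(ContingencyTable(*table))
            a, b, c, d = table
            t22 = sm.stats.Table2x2([[a, b], [c, d]])
            assert est.ror == pytest.approx(t22.oddsratio, rel=1e-12)
            lo, hi = t22.oddsratio_confint(0.05)
            # Table2x2 uses the exact normal quantile; we use the conventional 1.96
            assert est.ci_low == pytest.approx(lo, rel=1e-3)
            assert est.ci_high == pytest.approx(hi, rel=1e-3)

    def test_zero_cell_undefined_by_default(self, caplog):
        with caplog.at_level("INFO", logger="pvsignal"):
            est = compute_ror(ContingencyTable(0, 10, 5, 5))
        assert est.undefined and math.isnan(est.ror) and not est.is_signal

    def test_zero_cell_continuity_correction(self):
        est = compute_ror(ContingencyTable(0, 10, 5, 5), continuity_correction=True)
        assert not est.undefined
        assert est.ror == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_literal_rule_variant(self):
        # strong disproportion: both readings flag it
        t = ContingencyTable(50, 50, 5, 95)
        assert compute_ror(t, rule="ci").is_signal
        assert compute_ror(t, rule="literal").is_signal
        # weak: CI rule declines, literal reading of "ROR - 1.96 SE > 1" differs
        weak = compute_ror(ContingencyTable(12, 88, 10, 90), rule="literal")
        assert weak.is_signal == (weak.ror - 1.96 * weak.se_log > 1)
        with pytest.raises(ValueError):
            compute_ror(t, rule="bogus")


class TestNormalizedFrequency:
    def test_rounds_half_up(self):
        assert normalized_frequency(1, 200_000) == 1  # 0.5 rounds up
        assert normalized_frequency(0, 1000) == 0
        assert normalized_frequency(1000, 1000) == 100_000

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            normalized_frequency(1, 0)
        with pytest.raises(ValueError):
            normalized_frequency(5, 4)


def _long(pairs: list[tuple[str, str]]) -> pd.DataFrame:
    return pd.DataFrame(pairs, columns=["report_id", "preferred_term"])


class TestBuildContingency:
    def test_enumerable_example(self):
        long = _long([("r1", "Pyrexia"), ("r2", "Crying"), ("r3", "Pyrexia")])
        t = build_contingency(long, {"r1", "r2"}, {"r3"}, "Pyrexia")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 0)

    def test_absent_pt(self):
        long = _long([("r1", "Pyrexia")])
        t = build_contingency(long, {"r1", "r2"}, {"r3", "r4", "r5"}, "Melaena")
        assert (t.a, t.b, t.c, t.d) == (0, 2, 0, 3)

    def test_duplicate_listing_counts_once(self):
        long = _long([("r1", "Pyrexia"), ("r1", "Pyrexia")])
        t = build_contingency(long, {"r1"}, {"r2"}, "Pyrexia")
        assert t.a == 1

    def test_overlapping_ids_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            build_contingency(_long([]), {"r1"}, {"r1", "r2"}, "Pyrexia")


class TestScreenAndRank:
    def test_screen_counts_and_order(self):
        long = _long(
            [("t1", "Pyrexia"), ("t2", "Pyrexia"), ("t2", "Crying"),
             ("c1", "Pyrexia"), ("c2", "Crying"), ("c3", "Rash")]
        )
        results = screen_stratum(long, {"t1", "t2"}, {"c1", "c2", "c3"}, "S")
        assert [r.preferred_term for r in results] == ["Pyrexia", "Crying"]
        assert results[0].a == 2
        assert results[0].frequency_per_100k == 100_000
        assert results[0].stratum == "S"

    def test_denominator_override(self):
        long = _long([("t1", "Pyrexia")])
        (res,) = screen_stratum(long, {"t1", "t2"}, {"c1"}, stratum_denominator=1000)
        assert res.frequency_per_100k == 100  # 1/1000

    def test_empty_target_stratum(self):
        assert screen_stratum(_long([("c1", "Pyrexia")]), set(), {"c1"}) == []

    def test_rank_tie_break_lexicographic(self):
        long = _long(
            [(f"t{i}", "Pallor") for i in range(5)]
            + [(f"t{i}", "Crying") for i in range(5)]
            + [(f"t{i}", "Xerosis") for i in range(3)]
            + [("c1", "Pallor"), ("c1", "Crying"), ("c1", "Xerosis")]
        )
        results = screen_stratum(long, {f"t{i}" for i in range(5)}, {"c1"})
        top = rank_top(results, 2)
        assert [r.preferred_term for r in top] == ["Crying", "Pallor"]

    def test_rank_k_bounds(self):
        long = _long([("t1", "Pyrexia")])
        results = screen_stratum(long, {"t1"}, {"c1"})
        assert rank_top(results, 10) == results  # k > |results|
        with pytest.raises(ValueError):
            rank_top(results, 0)


class TestOracleEquivalence:
    def test_recount_oracle_on_small_synthetic_data(self, small_population):
        """On a generated population, screen counts and RORs match a
        brute-force per-report recount with exact rational arithmetic."""
        truth = small_population.truth
        long = truth.assignments
        syn = truth.reports.loc[truth.reports["vaccine"] == "SYNFLORIX", "report_id"]
        oth = truth.reports.loc[truth.reports["vaccine"] == "OTHER", "report_id"]
        tids, cids = set(syn), set(oth)
        results = screen_stratum(long, tids, cids)
        pts_by_report: dict[str, set[str]] = {}
        for rid, pt in long.itertuples(index=False):
            pts_by_report.setdefault(rid, set()).add(pt)
        for res in results[:40]:
            a = sum(1 for r in tids if res.preferred_term in pts_by_report.get(r, ()))
            c = sum(1 for r in cids if res.preferred_term in pts_by_report.get(r, ()))
            b, d = len(tids) - a, len(cids) - c
            assert res.a == a
            if min(a, b, c, d) > 0:
                oracle = Fraction(a * d, b * c)
                assert res.ror == pytest.approx(float(oracle), rel=1e-12)
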