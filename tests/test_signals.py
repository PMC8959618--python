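import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from srsignal.signals import (
    ContingencyTable,
    SignalConfig,
    bcpnn_stats,
    build_table,
    chi2_stat,
    compute_signal,
    compute_signals,
    enumerate_tables,
    probe_consistent_tables,
    prr_stats,
    rank_signals,
    ror_stats,
)

from .conftest import make_combo

WORKED = ContingencyTable(5, 15, 20, 160)
INDEPENDENT = ContingencyTable(10, 90, 90, 810)  # ad = bc

positive_cells = st.integers(min_value=1, max_value=2000)


@st.composite
def valid_tables(draw):
    return ContingencyTable(
        draw(positive_cells), draw(positive_cells),
        draw(positive_cells), draw(positive_cells),
    )


class TestBuildTable:
    TOY = [
        make_combo("r1", "D", "X"), make_combo("r1", "D", "Y"),
        make_combo("r2", "D", "X"), make_combo("r3", "E", "X"),
        make_combo("r4", "E", "Z"), make_combo("r5", "F", "Y"),
    ]

    def test_hand_enumeration(self):
        t = build_table(self.TOY, "D", "X")
        assert (t.a, t.b, t.c, t.d, t.n) == (2, 1, 1, 2, 6)

    def test_absent_drug_gives_zero_row(self):
        t = build_table(self.TOY, "Q", "X")
        assert (t.a, t.b) == (0, 0)
        assert t.c == 3  # all X combinations
        assert t.n == 6

    def test_partition_property(self):
        tables = enumerate_tables(self.TOY)
        assert sum(t.a for t in tables.values()) == len(self.TOY)

    def test_drug_margin_partition(self):
        tables = enumerate_tables(self.TOY)
        for drug in ("D", "E", "F"):
            drug_total = sum(
                t.a for (d, _), t in tables.items() if d == drug
            )
            any_table = next(t for (d, _), t in tables.items() if d == drug)
            assert drug_total == any_table.a + any_table.b

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestRor:
    def test_worked_example(self):
        r = ror_stats(WORKED)
        assert r.value == pytest.approx(2.667, abs=1e-3)
        assert r.li95 == pytest.approx(0.876, abs=1e-3)

    def test_independence_is_exactly_one(self):
        assert ror_stats(INDEPENDENT).value == pytest.approx(1.0, abs=0)

    def test_scaling_preserves_point_and_narrows_ci(self):
        base = ror_stats(WORKED)
        scaled = ror_stats(ContingencyTable(50, 150, 200, 1600))
        assert scaled.value == pytest.approx(base.value, rel=1e-12)
        assert scaled.ui95 - scaled.li95 < base.ui95 - base.li95

    def test_zero_cell_non_computable(self):
        r = ror_stats(ContingencyTable(0, 5, 5, 5))
        assert not r.computable
        assert r.reason == "zero cell"
        assert r.value is None

    @given(valid_tables())
    @settings(max_examples=100, deadline=None)
    def test_matches_direct_arithmetic(self, t):
        r = ror_stats(t)
        assert r.value == pytest.approx((t.a / t.c) / (t.b / t.d), rel=1e-12)


class TestPrr:
    def test_worked_example(self):
        r = prr_stats(WORKED)
        assert r.value == pytest.approx(2.25, abs=1e-3)
        assert r.li95 == pytest.approx(0.948, abs=1e-3)

    def test_independence_is_exactly_one(self):
        assert prr_stats(INDEPENDENT).value == pytest.approx(1.0, abs=0)

    def test_monotone_in_a(self):
        values = [
            prr_stats(ContingencyTable(a, 15, 20, 160)).value for a in (1, 5, 10, 40)
        ]
        assert values == sorted(values)
        assert len(set(values)) == len(values)

    @given(valid_tables())
    @settings(max_examples=100, deadline=None)
    def test_matches_direct_arithmetic(self, t):
        r = prr_stats(t)
        expected = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
        assert r.value == pytest.approx(expected, rel=1e-12)


class TestChi2:
    def test_worked_example_both_variants(self):
        assert chi2_stat(WORKED, corrected=False)[0] == pytest.approx(3.1746, abs=1e-3)
        assert chi2_stat(WORKED, corrected=True)[0] == pytest.approx(2.0317, abs=1e-3)

    def test_independence_is_zero(self):
        assert chi2_stat(INDEPENDENT, corrected=False)[0] == pytest.approx(0, abs=0)
        assert chi2_stat(INDEPENDENT, corrected=True)[0] == pytest.approx(0, abs=0)

    def test_yates_clamps_at_zero(self):
        # near-independence where |ad-bc| < n/2: uncorrected formula would be
        # positive, the corrected one must clamp to 0
        t = ContingencyTable(10, 90, 91, 810)
        assert abs(10 * 810 - 90 * 91) < t.n / 2
        assert chi2_stat(t, corrected=True)[0] == 0.0

    def test_zero_margin_non_computable(self):
        value, reason = chi2_stat(ContingencyTable(0, 0, 5, 5))
        assert value is None
        assert reason == "zero margin"

    @given(valid_tables())
    @settings(max_examples=200, deadline=None)
    def test_uncorrected_matches_scipy_pearson(self, t):
        ours = chi2_stat(t, corrected=False)[0]
        ref = sps.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=False
        ).statistic
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


class TestBcpnn:
    def test_worked_example(self):
        ic = bcpnn_stats(WORKED)
        assert ic.eic == pytest.approx(1.136, abs=1e-3)
        assert ic.vic == pytest.approx(0.4928, abs=1e-3)
        assert ic.li95 == pytest.approx(-0.268, abs=1e-3)

    def test_zero_a_is_finite(self):
        ic = bcpnn_stats(ContingencyTable(0, 10, 10, 100))
        assert ic.computable
        assert math.isfinite(ic.eic)

    @pytest.mark.parametrize("variant", ["n4", "plain"])
    def test_asymptotic_independence_limit(self, variant):
        # a = (a+b)(a+c)/n held at independence, n = 1e6
        t = ContingencyTable(10_000, 90_000, 90_000, 810_000)
        assert t.n == 10**6
        assert t.a * t.d == t.b * t.c
        ic = bcpnn_stats(t, variant=variant)
        assert ic.eic == pytest.approx(0.0, abs=0.01)

    def test_overflow_safe_for_large_n(self):
        ic = bcpnn_stats(ContingencyTable(10**6, 10**8, 10**7, 10**9))
        assert math.isfinite(ic.eic)
        assert math.isfinite(ic.vic)


class TestCriteria:
    def test_small_a_blocks_frequentist_flags(self):
        # a=2 with overwhelming disproportionality still not flagged
        result = compute_signal(ContingencyTable(2, 1, 1, 10000))
        assert result.ror.li95 > 1
        assert not result.flag_ror
        assert not result.flag_prr
        assert not result.flag_mhra

    def test_worked_example_all_flags_false(self):
        result = compute_signal(WORKED)
        assert not any(
            [result.flag_ror, result.flag_prr, result.flag_mhra, result.flag_bcpnn]
        )

    def test_independence_never_flagged(self):
        result = compute_signal(INDEPENDENT)
        assert not result.flag_consensus
        assert not any(
            [result.flag_ror, result.flag_prr, result.flag_mhra, result.flag_bcpnn]
        )

    def test_strong_signal_flags_all(self):
        result = compute_signal(ContingencyTable(30, 70, 100, 9800))
        assert result.flag_ror and result.flag_prr
        assert result.flag_mhra and result.flag_bcpnn
        assert result.flag_consensus

    def test_flags_pure_function_of_table(self):
        t = ContingencyTable(30, 70, 100, 9800)
        first = compute_signal(t)
        second = compute_signal(ContingencyTable(30, 70, 100, 9800))
        assert (first.flag_ror, first.flag_prr, first.flag_mhra,
                first.flag_bcpnn, first.flag_consensus) == (
            second.flag_ror, second.flag_prr, second.flag_mhra,
            second.flag_bcpnn, second.flag_consensus)

    def test_non_computable_stats_block_flags(self):
        result = compute_signal(ContingencyTable(5, 0, 3, 100))
        assert not result.flag_ror
        assert not result.flag_consensus

    def test_pearson_variant_config(self):
        config = SignalConfig(chi2_variant="pearson")
        result = compute_signal(WORKED, config=config)
        assert result.chi2 == pytest.approx(3.1746, abs=1e-3)


class TestRanking:
    @staticmethod
    def _positive(drug, pt, a):
        # strong table scaled so PRR differs with a
        return compute_signal(
            ContingencyTable(a, 100 - a, 50, 10000), drug=drug, pt=pt
        )

    def test_sorted_by_prr_descending(self):
        results = [self._positive("d1", "x", 10), self._positive("d2", "y", 30),
                   self._positive("d3", "z", 20)]
        ranked = rank_signals(results)
        prrs = [r.prr.value for r in ranked]
        assert prrs == sorted(prrs, reverse=True)

    def test_empty_input(self):
        assert rank_signals([]) == []

    def test_deterministic_tie_break(self):
        a = self._positive("beta", "x", 20)
        b = self._positive("alpha", "x", 20)
        assert [r.drug for r in rank_signals([a, b])] == ["alpha", "beta"]
        assert [r.drug for r in rank_signals([b, a])] == ["alpha", "beta"]


class TestProbe:
    def test_probe_finds_planted_table(self):
        # plant a table, compute its stats, search for consistent tables
        t = ContingencyTable(12, 188, 300, 9500)
        result = compute_signal(t)
        hits = probe_consistent_tables(
            t.n,
            ror_li95=result.ror.li95,
            prr=result.prr.value,
            prr_li95=result.prr.li95,
            chi2=result.chi2,
            ic_li95=result.ic.li95,
            max_a=20,
            max_row=400,
            max_col=800,
        )
        assert t in hits
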