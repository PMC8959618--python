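import datetime

import pytest

from srsignal.descriptive import (
    drug_seriousness_table,
    onset_distribution,
    outcome_table,
    percentage,
    pt_table,
    soc_table,
    yearly_trend,
)
from srsignal.records import APDClass, Outcome

from .conftest import make_combo, make_report


class TestPercentage:
    @pytest.mark.parametrize(
        "freq,den,expected",
        [
            (298, 3363, 8.86),
            (275, 2970, 9.26),
            (1875, 3953, 47.43),
            (947, 3953, 23.96),
            (587 + 2593, 3363, 94.56),
            (7, 43, 16.28),
            (99, 1083, 9.14),
            (2593, 3363, 77.10),
        ],
    )
    def test_half_up_two_decimals(self, freq, den, expected):
        assert percentage(freq, den) == expected

    def test_half_up_at_exact_midpoint(self):
        assert percentage(125, 1000) == 12.50
        assert percentage(1, 800) == 0.13  # 0.125 rounds up

    def test_zero_denominator(self):
        assert percentage(5, 0) == 0.0


class TestYearlyTrend:
    def test_zero_filled_window(self):
        reports = [make_report(report_id="a", year=2017)]
        rows = yearly_trend(reports, (2016, 2018))
        assert [(r.year, r.count) for r in rows] == [(2016, 0), (2017, 1), (2018, 0)]

    def test_all_non_serious_proportions_zero(self):
        reports = [make_report(report_id=str(i), year=2018) for i in range(5)]
        rows = yearly_trend(reports, (2018, 2018))
        assert rows[0].serious_pct == 0.0

    def test_single_year_dataset_without_window(self):
        rows = yearly_trend([make_report(year=2019)])
        assert len(rows) == 1
        assert rows[0].year == 2019


def _onset_report(rid, delay_days):
    start = datetime.date(2018, 3, 1)
    return make_report(
        report_id=rid,
        suspected=("risperidone",),
        reactions=("Tremor",),
        start_date=start,
        onset_dates=[start + datetime.timedelta(days=delay_days)],
    )


class TestOnsetDistribution:
    @pytest.mark.parametrize(
        "delay,label",
        [(0, "same day"), (1, "1-7 d"), (7, "1-7 d"), (8, "8-30 d"),
         (30, "8-30 d"), (31, "31-90 d"), (90, "31-90 d"), (91, ">90 d")],
    )
    def test_bin_boundaries(self, drug_dict, delay, label):
        dist = onset_distribution([_onset_report("r", delay)], drug_dict)
        hit = {row.label: row.frequency for row in dist.table.rows}
        assert hit[label] == 1

    def test_missing_onset_counted_separately(self, drug_dict):
        report = make_report(start_date=datetime.date(2018, 3, 1), onset_dates=[None])
        dist = onset_distribution([report], drug_dict)
        assert dist.n_missing == 1
        assert dist.table.denominator == 0

    def test_negative_delay_flagged_not_binned(self, drug_dict):
        dist = onset_distribution([_onset_report("r", -3)], drug_dict)
        assert dist.n_negative == 1
        assert dist.table.denominator == 0


class TestDrugSeriousness:
    def test_paper_row_arithmetic(self, drug_dict):
        reports = [
            make_report(report_id=f"s{i}", suspected=("chlorpromazine",), serious=True)
            for i in range(7)
        ] + [
            make_report(report_id=f"n{i}", suspected=("chlorpromazine",), serious=False)
            for i in range(36)
        ]
        rows = drug_seriousness_table(reports, drug_dict)
        row = next(r for r in rows if r.label == "chlorpromazine")
        assert (row.serious, row.total, row.serious_pct) == (7, 43, 16.28)

    def test_class_rows_sum_member_drugs(self, drug_dict):
        reports = [
            make_report(report_id="1", suspected=("risperidone",), serious=True),
            make_report(report_id="2", suspected=("clozapine",)),
            make_report(report_id="3", suspected=("haloperidol",)),
        ]
        rows = drug_seriousness_table(reports, drug_dict)
        atypical = next(r for r in rows if r.label == "atypical")
        assert atypical.is_class_row
        assert atypical.total == 2
        assert atypical.serious == 1
        typical = next(r for r in rows if r.label == "typical")
        assert typical.total == 1

    def test_multi_apd_report_counts_in_each_drug_row(self, drug_dict):
        report = make_report(suspected=("risperidone", "haloperidol"))
        rows = drug_seriousness_table([report], drug_dict)
        assert next(r for r in rows if r.label == "risperidone").total == 1
        assert next(r for r in rows if r.label == "haloperidol").total == 1

    def test_zero_serious_drug(self, drug_dict):
        rows = drug_seriousness_table(
            [make_report(suspected=("sulpiride",))], drug_dict
        )
        row = next(r for r in rows if r.label == "sulpiride")
        assert row.serious == 0
        assert row.serious_pct == 0.0


class TestSocPtTables:
    def test_soc_percentage_paper_arithmetic(self):
        combos = [
            make_combo(f"r{i}", "d", f"pt{i}", soc="Nervous system disorders")
            for i in range(1875)
        ] + [
            make_combo(f"q{i}", "d", f"qt{i}", soc=f"Other {i % 2}")
            for i in range(3953 - 1875)
        ]
        table = soc_table(combos)
        top = table.rows[0]
        assert (top.label, top.frequency, top.percentage) == (
            "Nervous system disorders", 1875, 47.43,
        )

    def test_pt_percentage_paper_arithmetic(self):
        combos = [
            make_combo(f"r{i}", "d", "Extrapyramidal disorder") for i in range(947)
        ] + [make_combo(f"q{i}", "d", f"pt{i}") for i in range(3953 - 947)]
        table = pt_table(combos)
        top = table.rows[0]
        assert (top.frequency, top.percentage) == (947, 23.96)

    def test_class_filter_changes_denominator(self):
        combos = [
            make_combo("r1", "d", "x", apd_class=APDClass.TYPICAL),
            make_combo("r2", "d", "x", apd_class=APDClass.TYPICAL),
            make_combo("r3", "e", "y", apd_class=APDClass.ATYPICAL),
        ]
        typical = pt_table(combos, apd_class=APDClass.TYPICAL)
        assert typical.denominator == 2
        assert typical.rows[0].percentage == 100.0

    def test_top_k_keeps_full_denominator(self):
        combos = [make_combo(f"r{i}", "d", f"pt{i % 5}") for i in range(20)]
        table = pt_table(combos, top=2)
        assert len(table.rows) == 2
        assert table.denominator == 20

    def test_empty_set(self):
        assert soc_table([]).rows == ()

    def test_exhaustive_sums_to_denominator(self):
        combos = [make_combo(f"r{i}", "d", f"pt{i % 3}") for i in range(11)]
        table = pt_table(combos)
        assert sum(r.frequency for r in table.rows) == table.denominator


class TestOutcomeTable:
    def _reports(self, spec):
        out = []
        i = 0
        for outcome, count in spec.items():
            for _ in range(count):
                out.append(make_report(report_id=f"r{i}", outcome=outcome))
                i += 1
        return out

    def test_paper_arithmetic(self):
        reports = self._reports(
            {
                Outcome.RELIEVED: 587,
                Outcome.CURED: 2593,
                Outcome.NOT_RELIEVED: 73,
                Outcome.SEQUELAE: 1,
                Outcome.MISSING: 109,
            }
        )
        table = outcome_table(reports)
        by_label = {r.label: r for r in table.rows}
        assert table.denominator == 3363
        assert by_label["Cured"].percentage == 77.10
        assert by_label["Relieved"].percentage == 17.45
        assert by_label["Not relieved"].percentage == 2.17
        assert by_label["Left with sequelae"].percentage == 0.03
        assert by_label["Missing"].percentage == 3.24
        improved = by_label["Relieved"].frequency + by_label["Cured"].frequency
        assert percentage(improved, table.denominator) == 94.56

    def test_all_missing(self):
        table = outcome_table(self._reports({Outcome.MISSING: 4}))
        by_label = {r.label: r for r in table.rows}
        assert by_label["Missing"].percentage == 100.0

    def test_percentages_rederive_from_frequencies(self):
        table = outcome_table(self._reports({Outcome.CURED: 3, Outcome.MISSING: 4}))
        for row in table.rows:
            assert row.percentage == percentage(row.frequency, table.denominator)
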