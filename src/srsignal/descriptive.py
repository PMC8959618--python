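"""Descriptive surfaces: yearly trend, onset delays, seriousness, SOC/PT
frequencies and outcome tallies.

All percentages are 100*frequency/denominator rounded half-up to two
decimals, computed exactly in decimal arithmetic so printed-table arithmetic
is reproduced bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .preprocess import DrugEventCombination
from .records import ADRReport, APDClass, DrugDictionary, DrugRole, Outcome

#: Default onset-delay bins in days: [lo, hi] inclusive, last bin open-ended.
DEFAULT_ONSET_BINS = (
    ("same day", 0, 0),
    ("1-7 d", 1, 7),
    ("8-30 d", 8, 30),
    ("31-90 d", 31, 90),
    (">90 d", 91, None),
)


def percentage(frequency: int | float, denominator: int | float) -> float:
    """100*frequency/denominator, rounded half-up to 2 decimals."""
    if denominator == 0:
        return 0.0
    value = Decimal(frequency) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FrequencyRow:
    label: str
    frequency: int
    percentage: float


@dataclass(frozen=True)
class FrequencyTable:
    """Labelled counts with percentages of a stated denominator."""

    rows: tuple[FrequencyRow, ...]
    denominator: int
    denominator_basis: str  # "reports" | "combinations" | "reactions"

    def as_dict(self) -> dict:
        return {
            "denominator": self.denominator,
            "denominator_basis": self.denominator_basis,
            "rows": [
                {"label": r.label, "frequency": r.frequency, "percentage": r.percentage}
                for r in self.rows
            ],
        }


def _freq_table(
    counts: dict[str, int], denominator: int, basis: str, order: Sequence[str] | None = None
) -> FrequencyTable:
    labels = list(order) if order is not None else sorted(
        counts, key=lambda k: (-counts[k], k)
    )
    rows = tuple(
        FrequencyRow(label, counts.get(label, 0), percentage(counts.get(label, 0), denominator))
        for label in labels
    )
    return FrequencyTable(rows=rows, denominator=denominator, denominator_basis=basis)


@dataclass(frozen=True)
class YearRow:
    year: int
    count: int
    serious_count: int
    serious_pct: float


def yearly_trend(
    reports: Sequence[ADRReport], year_window: Optional[tuple[int, int]] = None
) -> list[YearRow]:
    """Report counts and serious proportions per calendar year, zero-filled."""
    counts: dict[int, int] = {}
    serious: dict[int, int] = {}
    for r in reports:
        y = r.report_date.year
        counts[y] = counts.get(y, 0) + 1
        serious[y] = serious.get(y, 0) + int(r.serious)
    if year_window is None:
        if not counts:
            return []
        year_window = (min(counts), max(counts))
    return [
        YearRow(
            year=y,
            count=counts.get(y, 0),
            serious_count=serious.get(y, 0),
            serious_pct=percentage(serious.get(y, 0), counts.get(y, 0)),
        )
        for y in range(year_window[0], year_window[1] + 1)
    ]


@dataclass(frozen=True)
class OnsetDistribution:
    table: FrequencyTable
    n_missing: int
    n_negative: int


def onset_delay_days(report: ADRReport, drug_dict: DrugDictionary) -> list[Optional[int]]:
    """Per-reaction delay: onset minus earliest suspected-antipsychotic start."""
    starts = []
    for drug in report.drugs:
        if drug.role is not DrugRole.SUSPECTED or drug.start_date is None:
            continue
        entry = drug_dict.lookup(drug.raw_name)
        if entry is not None and entry.apd_class is not APDClass.NON_APD:
            starts.append(drug.start_date)
    if not starts:
        return [None] * len(report.reactions)
    start = min(starts)
    return [
        None if rx.onset_date is None else (rx.onset_date - start).days
        for rx in report.reactions
    ]


def onset_distribution(
    reports: Sequence[ADRReport],
    drug_dict: DrugDictionary,
    bins=DEFAULT_ONSET_BINS,
) -> OnsetDistribution:
    """Bin per-reaction onset delays; missing or negative delays are counted
    separately and excluded from the denominator."""
    counts = {label: 0 for label, _, _ in bins}
    n_missing = 0
    n_negative = 0
    for report in reports:
        for delay in onset_delay_days(report, drug_dict):
            if delay is None:
                n_missing += 1
                continue
            if delay < 0:
                n_negative += 1
                continue
            for label, lo, hi in bins:
                if delay >= lo and (hi is None or delay <= hi):
                    counts[label] += 1
                    break
    denominator = sum(counts.values())
    table = _freq_table(counts, denominator, "reactions", order=[b[0] for b in bins])
    return OnsetDistribution(table=table, n_missing=n_missing, n_negative=n_negative)


@dataclass(frozen=True)
class SeriousnessRow:
    label: str  # drug generic name or class name
    is_class_row: bool
    non_serious: int
    serious: int
    total: int
    serious_pct: float


def _seriousness_row(label: str, is_class: bool, serious: int, total: int) -> SeriousnessRow:
    return SeriousnessRow(
        label=label,
        is_class_row=is_class,
        non_serious=total - serious,
        serious=serious,
        total=total,
        serious_pct=percentage(serious, total),
    )


def drug_seriousness_table(
    reports: Sequence[ADRReport], drug_dict: DrugDictionary
) -> list[SeriousnessRow]:
    """Per-drug and per-class report tallies split by seriousness.

    A report with several suspected antipsychotics counts once in each drug's
    row; class rows are the sums of their member drug rows. Within a class,
    drugs sort by report count descending.
    """
    totals: dict[str, int] = {}
    serious: dict[str, int] = {}
    classes: dict[str, APDClass] = {}
    for report in reports:
        seen: set[str] = set()
        for drug in report.suspected_drugs():
            entry = drug_dict.lookup(drug.raw_name)
            if entry is None or entry.apd_class is APDClass.NON_APD:
                continue
            if entry.generic_name in seen:
                continue
            seen.add(entry.generic_name)
            totals[entry.generic_name] = totals.get(entry.generic_name, 0) + 1
            serious[entry.generic_name] = serious.get(entry.generic_name, 0) + int(
                report.serious
            )
            classes[entry.generic_name] = entry.apd_class
    rows: list[SeriousnessRow] = []
    for cls in (APDClass.ATYPICAL, APDClass.TYPICAL):
        members = sorted(
            (g for g, c in classes.items() if c is cls),
            key=lambda g: (-totals[g], g),
        )
        if not members:
            continue
        rows.append(
            _seriousness_row(
                cls.value,
                True,
                sum(serious[g] for g in members),
                sum(totals[g] for g in members),
            )
        )
        rows.extend(
            _seriousness_row(g, False, serious[g], totals[g]) for g in members
        )
    return rows


def soc_table(
    combinations: Sequence[DrugEventCombination], top: Optional[int] = None
) -> FrequencyTable:
    """Combination counts per primary SOC; denominator is all combinations."""
    counts: dict[str, int] = {}
    for combo in combinations:
        counts[combo.soc] = counts.get(combo.soc, 0) + 1
    table = _freq_table(counts, len(combinations), "combinations")
    if top is not None:
        table = FrequencyTable(table.rows[:top], table.denominator, table.denominator_basis)
    return table


def pt_table(
    combinations: Sequence[DrugEventCombination],
    apd_class: Optional[APDClass] = None,
    top: Optional[int] = None,
) -> FrequencyTable:
    """Combination counts per preferred term, optionally restricted to one
    antipsychotic class; the denominator is the in-scope combination count."""
    in_scope = [
        c for c in combinations if apd_class is None or c.apd_class is apd_class
    ]
    counts: dict[str, int] = {}
    for combo in in_scope:
        counts[combo.pt] = counts.get(combo.pt, 0) + 1
    table = _freq_table(counts, len(in_scope), "combinations")
    if top is not None:
        table = FrequencyTable(table.rows[:top], table.denominator, table.denominator_basis)
    return table


_OUTCOME_LABELS = {
    Outcome.RELIEVED: "Relieved",
    Outcome.CURED: "Cured",
    Outcome.NOT_RELIEVED: "Not relieved",
    Outcome.SEQUELAE: "Left with sequelae",
    Outcome.DEATH: "Death",
    Outcome.MISSING: "Missing",
}
_OUTCOME_ORDER = [
    Outcome.RELIEVED,
    Outcome.CURED,
    Outcome.NOT_RELIEVED,
    Outcome.SEQUELAE,
    Outcome.DEATH,
    Outcome.MISSING,
]


def outcome_table(reports: Sequence[ADRReport]) -> FrequencyTable:
    """Outcome tallies over all included reports (missing is its own row).

    The death row is emitted only when present, keeping the standard
    five-category layout otherwise.
    """
    counts: dict[str, int] = {}
    for report in reports:
        label = _OUTCOME_LABELS[report.outcome]
        counts[label] = counts.get(label, 0) + 1
    order = [
        _OUTCOME_LABELS[o]
        for o in _OUTCOME_ORDER
        if o is not Outcome.DEATH or counts.get(_OUTCOME_LABELS[o], 0) > 0
    ]
    return _freq_table(counts, len(reports), "reports", order=order)
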