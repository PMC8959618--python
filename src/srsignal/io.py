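"""Reading and writing the delimited-text dataset and dictionary formats.

A dataset on disk is three UTF-8 CSV files in long format:

``reports.csv``
    one row per report: ``report_id, sex, age, report_date, hospital_level,
    hospital_type, diagnoses, causality, serious, outcome`` (``diagnoses`` is
    ``|``-joined).
``drugs.csv``
    one row per drug on a report: ``report_id, raw_name, role, start_date``.
``reactions.csv``
    one row per reaction term: ``report_id, raw_term, onset_date``.

Dates are ISO-8601. A bare year is accepted and imputed to July 1; the
imputation is flagged on the record and the bare year is preserved when
writing, so read -> write -> read is the identity. Validation never silently
drops a record: every input report row either becomes an :class:`ADRReport`
or has at least one entry in the error log.
"""

from __future__ import annotations

import csv
import datetime
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .records import (
    ADRReport,
    APDClass,
    Causality,
    DictionaryError,
    DrugDictionary,
    DrugEntry,
    DrugRole,
    DrugUse,
    HospitalType,
    LabelKnowledge,
    Outcome,
    ReactionRecord,
    Sex,
    TermDictionary,
    TermEntry,
    normalize_key,
)

REPORT_COLUMNS = [
    "report_id",
    "sex",
    "age",
    "report_date",
    "hospital_level",
    "hospital_type",
    "diagnoses",
    "causality",
    "serious",
    "outcome",
]
DRUG_COLUMNS = ["report_id", "raw_name", "role", "start_date"]
REACTION_COLUMNS = ["report_id", "raw_term", "onset_date"]

_DIAGNOSIS_SEP = "|"


class SchemaError(ValueError):
    """A file is missing a mandatory column."""


@dataclass(frozen=True)
class RowError:
    """One row-level validation failure."""

    source: str
    row: int
    report_id: str
    message: str


@dataclass
class ReadResult:
    reports: list[ADRReport]
    errors: list[RowError]

    @property
    def n_input_rows(self) -> int:
        return len(self.reports) + len({e.report_id for e in self.errors})


def _parse_date(text: str) -> tuple[Optional[datetime.date], bool]:
    """Parse an ISO date or a bare year (imputed to July 1, flagged)."""
    text = text.strip()
    if not text:
        return None, False
    if len(text) == 4 and text.isdigit():
        return datetime.date(int(text), 7, 1), True
    return datetime.date.fromisoformat(text), False


def _format_date(date: Optional[datetime.date], imputed: bool) -> str:
    if date is None:
        return ""
    if imputed:
        return f"{date.year:04d}"
    return date.isoformat()


def _check_header(header: Sequence[str], required: Sequence[str], source: str) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{source}: missing mandatory column(s): {', '.join(missing)}")


def _read_rows(path: Path, required: Sequence[str]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path.name}: empty file, header expected")
        _check_header(reader.fieldnames, required, path.name)
        return list(reader)


def _parse_drug_row(row: dict[str, str]) -> DrugUse:
    start, imputed = _parse_date(row.get("start_date", "") or "")
    return DrugUse(
        raw_name=row["raw_name"].strip(),
        role=DrugRole(row["role"].strip().lower()),
        start_date=start,
        date_imputed=imputed,
    )


def _parse_reaction_row(row: dict[str, str]) -> ReactionRecord:
    onset, imputed = _parse_date(row.get("onset_date", "") or "")
    return ReactionRecord(
        raw_term=row["raw_term"].strip(),
        onset_date=onset,
        date_imputed=imputed,
    )


def _parse_report_row(
    row: dict[str, str],
    drugs: list[DrugUse],
    reactions: list[ReactionRecord],
) -> ADRReport:
    age_text = (row.get("age") or "").strip()
    report_date, date_imputed = _parse_date(row["report_date"])
    if report_date is None:
        raise ValueError("report_date is mandatory")
    diagnoses_text = (row.get("diagnoses") or "").strip()
    serious_text = row["serious"].strip().lower()
    if serious_text not in {"true", "false"}:
        raise ValueError(f"serious must be true/false, got {row['serious']!r}")
    if not drugs:
        raise ValueError("report has no valid drug rows")
    if not reactions:
        raise ValueError("report has no valid reaction rows")
    return ADRReport(
        report_id=row["report_id"].strip(),
        sex=Sex((row.get("sex") or "unknown").strip().lower() or "unknown"),
        age=float(age_text) if age_text else None,
        report_date=report_date,
        hospital_level=int(row["hospital_level"]),
        hospital_type=HospitalType(row["hospital_type"].strip().lower()),
        diagnoses=[d for d in diagnoses_text.split(_DIAGNOSIS_SEP) if d],
        drugs=drugs,
        reactions=reactions,
        causality=Causality(row["causality"].strip().lower()),
        serious=serious_text == "true",
        outcome=Outcome((row.get("outcome") or "missing").strip().lower() or "missing"),
        report_date_imputed=date_imputed,
    )


def read_reports(
    reports_path: str | Path,
    drugs_path: str | Path,
    reactions_path: str | Path,
) -> ReadResult:
    """Read a long-format dataset into validated :class:`ADRReport` records.

    Any parse failure on a report's parent row or any of its child rows drops
    the whole report and logs one :class:`RowError` per failure; the remaining
    reports preserve input order. Missing mandatory columns raise
    :class:`SchemaError`.
    """
    reports_path, drugs_path, reactions_path = (
        Path(reports_path),
        Path(drugs_path),
        Path(reactions_path),
    )
    report_rows = _read_rows(reports_path, REPORT_COLUMNS)
    drug_rows = _read_rows(drugs_path, DRUG_COLUMNS)
    reaction_rows = _read_rows(reactions_path, REACTION_COLUMNS)

    errors: list[RowError] = []
    bad_report_ids: set[str] = set()

    drugs_by_report: dict[str, list[DrugUse]] = {}
    for i, row in enumerate(drug_rows, start=2):
        rid = row["report_id"].strip()
        try:
            drugs_by_report.setdefault(rid, []).append(_parse_drug_row(row))
        except (ValueError, KeyError) as exc:
            errors.append(RowError(drugs_path.name, i, rid, str(exc)))
            bad_report_ids.add(rid)

    reactions_by_report: dict[str, list[ReactionRecord]] = {}
    for i, row in enumerate(reaction_rows, start=2):
        rid = row["report_id"].strip()
        try:
            reactions_by_report.setdefault(rid, []).append(_parse_reaction_row(row))
        except (ValueError, KeyError) as exc:
            errors.append(RowError(reactions_path.name, i, rid, str(exc)))
            bad_report_ids.add(rid)

    reports: list[ADRReport] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(report_rows, start=2):
        rid = (row.get("report_id") or "").strip()
        if rid in seen_ids:
            errors.append(
                RowError(reports_path.name, i, rid, f"duplicate report_id {rid!r}")
            )
            continue
        seen_ids.add(rid)
        if rid in bad_report_ids:
            errors.append(
                RowError(
                    reports_path.name, i, rid, "dropped: invalid drug/reaction row"
                )
            )
            continue
        try:
            reports.append(
                _parse_report_row(
                    row,
                    drugs_by_report.get(rid, []),
                    reactions_by_report.get(rid, []),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(RowError(reports_path.name, i, rid, str(exc)))
    return ReadResult(reports=reports, errors=errors)


def write_reports(
    reports: Sequence[ADRReport],
    reports_path: str | Path,
    drugs_path: str | Path,
    reactions_path: str | Path,
) -> None:
    """Write reports to the three-file long format (inverse of read_reports)."""
    with open(reports_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for r in reports:
            writer.writerow(
                [
                    r.report_id,
                    r.sex.value,
                    "" if r.age is None else f"{r.age:g}",
                    _format_date(r.report_date, r.report_date_imputed),
                    r.hospital_level,
                    r.hospital_type.value,
                    _DIAGNOSIS_SEP.join(r.diagnoses),
                    r.causality.value,
                    "true" if r.serious else "false",
                    r.outcome.value,
                ]
            )
    with open(drugs_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DRUG_COLUMNS)
        for r in reports:
            for d in r.drugs:
                writer.writerow(
                    [
                        r.report_id,
                        d.raw_name,
                        d.role.value,
                        _format_date(d.start_date, d.date_imputed),
                    ]
                )
    with open(reactions_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REACTION_COLUMNS)
        for r in reports:
            for rx in r.reactions:
                writer.writerow(
                    [
                        r.report_id,
                        rx.raw_term,
                        _format_date(rx.onset_date, rx.date_imputed),
                    ]
                )


def load_drug_dictionary(path: str | Path) -> DrugDictionary:
    rows = _read_rows(Path(path), ["raw_name", "generic_name", "atc_code", "apd_class"])
    entries: dict[str, DrugEntry] = {}
    for row in rows:
        entry = DrugEntry(
            generic_name=row["generic_name"].strip(),
            atc_code=row["atc_code"].strip(),
            apd_class=APDClass(row["apd_class"].strip().lower()),
        )
        nkey = normalize_key(row["raw_name"])
        if nkey in entries and entries[nkey] != entry:
            raise DictionaryError(
                f"conflicting duplicate drug mapping for {row['raw_name']!r}"
            )
        entries[nkey] = entry
    return DrugDictionary(entries)


def load_term_dictionary(path: str | Path) -> TermDictionary:
    rows = _read_rows(Path(path), ["raw_term", "pt", "soc"])
    entries: dict[str, TermEntry] = {}
    for row in rows:
        entry = TermEntry(pt=row["pt"].strip(), soc=row["soc"].strip())
        nkey = normalize_key(row["raw_term"])
        if nkey in entries and entries[nkey] != entry:
            raise DictionaryError(
                f"conflicting duplicate term mapping for {row['raw_term']!r}"
            )
        entries[nkey] = entry
    return TermDictionary(entries)


def load_label_knowledge(path: str | Path) -> LabelKnowledge:
    rows = _read_rows(Path(path), ["generic_name", "pt"])
    labeled: dict[str, set[str]] = {}
    for row in rows:
        labeled.setdefault(row["generic_name"].strip(), set()).add(row["pt"].strip())
    return LabelKnowledge(labeled)


def load_dictionaries(
    drug_path: str | Path,
    term_path: str | Path,
    label_path: str | Path,
) -> tuple[DrugDictionary, TermDictionary, LabelKnowledge]:
    """Load the drug-name, reaction-term, and product-label dictionaries."""
    return (
        load_drug_dictionary(drug_path),
        load_term_dictionary(term_path),
        load_label_knowledge(label_path),
    )
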