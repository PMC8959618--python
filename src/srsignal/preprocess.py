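"""Report filtering, name standardization, and drug-event expansion.

Reports are retained iff the report year falls in the study window, at least
one suspected drug standardizes to an antipsychotic, and the causality
assessment is in the accepted set. Exclusion reasons are assigned by the
first failing rule, checked in that fixed order, so logs are deterministic.

Retained reports are expanded into drug-event combinations: the full
cross-product of suspected antipsychotics by standardized reaction preferred
terms, deduplicated within each report. Suspected non-antipsychotic drugs
never generate combinations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .records import (
    ADRReport,
    APDClass,
    Causality,
    DrugDictionary,
    DrugRole,
    Sex,
    TermDictionary,
)


class ExclusionReason(str, enum.Enum):
    YEAR = "year"
    NOT_SUSPECTED = "not_suspected"
    CAUSALITY = "causality"


class Season(str, enum.Enum):
    SPRING = "spring"
    SUMMER = "summer"
    AUTUMN = "autumn"
    WINTER = "winter"


# Meteorological convention: Mar-May spring, Jun-Aug summer, Sep-Nov autumn,
# Dec-Feb winter.
_MONTH_TO_SEASON = {
    3: Season.SPRING, 4: Season.SPRING, 5: Season.SPRING,
    6: Season.SUMMER, 7: Season.SUMMER, 8: Season.SUMMER,
    9: Season.AUTUMN, 10: Season.AUTUMN, 11: Season.AUTUMN,
    12: Season.WINTER, 1: Season.WINTER, 2: Season.WINTER,
}

#: Age bins; half-open on the right except the last.
AGE_BINS = ("<18", "18-35", "35-65", ">=65")

#: Concurrent use of three or more medications (suspected + concomitant).
POLYPHARMACY_MIN_DRUGS = 3


def age_bin(age: Optional[float]) -> Optional[str]:
    if age is None:
        return None
    if age < 18:
        return "<18"
    if age < 35:
        return "18-35"
    if age < 65:
        return "35-65"
    return ">=65"


def season_of(month: int) -> Season:
    return _MONTH_TO_SEASON[month]


@dataclass(frozen=True, slots=True)
class Covariates:
    """Report-level covariates used by descriptive tables and the risk model."""

    sex: Sex
    age: Optional[float]
    age_bin: Optional[str]
    year: int
    season: Season
    hospital_level: int
    hospital_type: str
    polypharmacy: bool
    multiple_disease: bool
    apd_class: Optional[APDClass]  # atypical if any suspected atypical drug


def derive_covariates(
    report: ADRReport, drug_dict: Optional[DrugDictionary] = None
) -> Covariates:
    """Derive the modeled covariates from one report.

    The antipsychotic-class covariate is atypical if any suspected drug maps
    to an atypical antipsychotic, typical if any maps to a typical one, and
    None when no suspected drug is a recognized antipsychotic (or no
    dictionary is supplied).
    """
    apd_class: Optional[APDClass] = None
    if drug_dict is not None:
        classes = set()
        for drug in report.suspected_drugs():
            entry = drug_dict.lookup(drug.raw_name)
            if entry is not None and entry.apd_class is not APDClass.NON_APD:
                classes.add(entry.apd_class)
        if APDClass.ATYPICAL in classes:
            apd_class = APDClass.ATYPICAL
        elif APDClass.TYPICAL in classes:
            apd_class = APDClass.TYPICAL
    return Covariates(
        sex=report.sex,
        age=report.age,
        age_bin=age_bin(report.age),
        year=report.report_date.year,
        season=season_of(report.report_date.month),
        hospital_level=report.hospital_level,
        hospital_type=report.hospital_type.value,
        polypharmacy=len(report.drugs) >= POLYPHARMACY_MIN_DRUGS,
        multiple_disease=len(report.diagnoses) >= 2,
        apd_class=apd_class,
    )


def standardize_drug(
    raw_name: str, drug_dict: DrugDictionary
) -> Optional[tuple[str, APDClass]]:
    """Map a raw drug string to (generic name, class); None when unmapped."""
    entry = drug_dict.lookup(raw_name)
    if entry is None:
        return None
    return entry.generic_name, entry.apd_class


def standardize_term(
    raw_term: str, term_dict: TermDictionary
) -> Optional[tuple[str, str]]:
    """Map a raw reaction string to (preferred term, primary SOC); None when unmapped."""
    entry = term_dict.lookup(raw_term)
    if entry is None:
        return None
    return entry.pt, entry.soc


def _has_suspected_apd(report: ADRReport, drug_dict: DrugDictionary) -> bool:
    for drug in report.suspected_drugs():
        entry = drug_dict.lookup(drug.raw_name)
        if entry is not None and entry.apd_class is not APDClass.NON_APD:
            return True
    return False


@dataclass(frozen=True)
class Exclusion:
    report_id: str
    reason: ExclusionReason


def apply_inclusion_exclusion(
    reports: Sequence[ADRReport],
    drug_dict: DrugDictionary,
    year_window: tuple[int, int] = (2016, 2020),
    accepted_causality: frozenset[Causality] = frozenset(
        {Causality.CERTAIN, Causality.PROBABLE, Causality.POSSIBLE}
    ),
) -> tuple[list[ADRReport], list[Exclusion]]:
    """Apply the study inclusion/exclusion criteria.

    Rules, in order: report year inside ``year_window`` (inclusive), at least
    one suspected drug standardizes to an antipsychotic, causality in
    ``accepted_causality``. The exclusion log records the first failing rule.
    """
    if not accepted_causality:
        raise ValueError("accepted_causality must not be empty")
    start, end = year_window
    included: list[ADRReport] = []
    excluded: list[Exclusion] = []
    for report in reports:
        if not (start <= report.report_date.year <= end):
            excluded.append(Exclusion(report.report_id, ExclusionReason.YEAR))
        elif not _has_suspected_apd(report, drug_dict):
            excluded.append(Exclusion(report.report_id, ExclusionReason.NOT_SUSPECTED))
        elif report.causality not in accepted_causality:
            excluded.append(Exclusion(report.report_id, ExclusionReason.CAUSALITY))
        else:
            included.append(report)
    return included, excluded


@dataclass(frozen=True, slots=True)
class DrugEventCombination:
    """One (drug, preferred term) pair from one report — the mining unit."""

    report_id: str
    generic_drug: str
    apd_class: APDClass
    pt: str
    soc: str
    serious: bool
    covariates: Covariates


@dataclass
class ExpansionLog:
    """Bookkeeping from the report -> combination expansion."""

    unmapped_drugs: dict[str, int]
    unmapped_terms: dict[str, int]
    reports_without_pts: list[str]


def expand_combinations(
    reports: Sequence[ADRReport],
    drug_dict: DrugDictionary,
    term_dict: TermDictionary,
) -> tuple[list[DrugEventCombination], ExpansionLog]:
    """Expand included reports into deduplicated drug-event combinations.

    Each report contributes the cross-product of its suspected antipsychotics
    (standardized) and its standardized reaction PTs; duplicate
    (report, drug, PT) triples collapse to one. Unmapped names are tallied,
    and reports with no mappable reaction contribute nothing.
    """
    combos: list[DrugEventCombination] = []
    log = ExpansionLog(unmapped_drugs={}, unmapped_terms={}, reports_without_pts=[])
    for report in reports:
        cov = derive_covariates(report, drug_dict)
        apds: dict[str, APDClass] = {}
        for drug in report.suspected_drugs():
            mapped = standardize_drug(drug.raw_name, drug_dict)
            if mapped is None:
                log.unmapped_drugs[drug.raw_name] = (
                    log.unmapped_drugs.get(drug.raw_name, 0) + 1
                )
                continue
            generic, cls = mapped
            if cls is not APDClass.NON_APD:
                apds.setdefault(generic, cls)
        pts: dict[str, str] = {}
        for reaction in report.reactions:
            mapped = standardize_term(reaction.raw_term, term_dict)
            if mapped is None:
                log.unmapped_terms[reaction.raw_term] = (
                    log.unmapped_terms.get(reaction.raw_term, 0) + 1
                )
                continue
            pt, soc = mapped
            pts.setdefault(pt, soc)
        if not pts:
            log.reports_without_pts.append(report.report_id)
            continue
        for generic in sorted(apds):
            for pt in sorted(pts):
                combos.append(
                    DrugEventCombination(
                        report_id=report.report_id,
                        generic_drug=generic,
                        apd_class=apds[generic],
                        pt=pt,
                        soc=pts[pt],
                        serious=report.serious,
                        covariates=cov,
                    )
                )
    return combos, log
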