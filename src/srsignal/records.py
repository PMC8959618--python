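"""Domain record types for spontaneous ADR report datasets.

A dataset is a collection of :class:`ADRReport` objects, each carrying the
patient context, the drugs taken (suspected vs concomitant), the reaction
terms, a causality assessment, a seriousness flag, and an outcome. Raw drug
and reaction strings are standardized through :class:`DrugDictionary` and
:class:`TermDictionary`; product-label expectedness is encoded in
:class:`LabelKnowledge`.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class HospitalType(str, enum.Enum):
    PSYCHIATRIC = "psychiatric"
    GENERAL = "general"


class DrugRole(str, enum.Enum):
    SUSPECTED = "suspected"
    CONCOMITANT = "concomitant"


class Causality(str, enum.Enum):
    CERTAIN = "certain"
    PROBABLE = "probable"
    POSSIBLE = "possible"
    UNLIKELY = "unlikely"
    IMPOSSIBLE = "impossible"


#: Causality levels that keep a report in scope for signal mining.
ACCEPTED_CAUSALITY = frozenset(
    {Causality.CERTAIN, Causality.PROBABLE, Causality.POSSIBLE}
)


class Outcome(str, enum.Enum):
    CURED = "cured"
    RELIEVED = "relieved"
    NOT_RELIEVED = "not_relieved"
    SEQUELAE = "sequelae"
    DEATH = "death"
    MISSING = "missing"


class APDClass(str, enum.Enum):
    TYPICAL = "typical"
    ATYPICAL = "atypical"
    NON_APD = "non_apd"


@dataclass(slots=True)
class DrugUse:
    """One drug entry on a report.

    ``date_imputed`` marks a year-only start date that was imputed to July 1;
    the original year is preserved on round-trip.
    """

    raw_name: str
    role: DrugRole
    start_date: Optional[datetime.date] = None
    date_imputed: bool = False


@dataclass(slots=True)
class ReactionRecord:
    """One reaction term on a report, with its (possibly imputed) onset date."""

    raw_term: str
    onset_date: Optional[datetime.date] = None
    date_imputed: bool = False


@dataclass(slots=True)
class ADRReport:
    """One spontaneous ADR case report."""

    report_id: str
    sex: Sex
    age: Optional[float]
    report_date: datetime.date
    hospital_level: int
    hospital_type: HospitalType
    diagnoses: list[str]
    drugs: list[DrugUse]
    reactions: list[ReactionRecord]
    causality: Causality
    serious: bool
    outcome: Outcome
    report_date_imputed: bool = False

    def suspected_drugs(self) -> list[DrugUse]:
        return [d for d in self.drugs if d.role is DrugRole.SUSPECTED]

    def concomitant_drugs(self) -> list[DrugUse]:
        return [d for d in self.drugs if d.role is DrugRole.CONCOMITANT]


def normalize_key(raw: str) -> str:
    """Case- and whitespace-insensitive dictionary key."""
    return " ".join(raw.split()).lower()


@dataclass(frozen=True)
class DrugEntry:
    generic_name: str
    atc_code: str
    apd_class: APDClass


class DictionaryError(ValueError):
    """Raised when a dictionary file violates its invariants."""


class DrugDictionary:
    """Raw drug name -> (generic name, ATC code, antipsychotic class).

    Lookups are case/whitespace-insensitive. Every generic whose ATC code
    starts with ``N05A`` must be classed typical or atypical; anything else
    must be ``non_apd``.
    """

    def __init__(self, entries: Mapping[str, DrugEntry]):
        self._entries: dict[str, DrugEntry] = {}
        for raw, entry in entries.items():
            key = normalize_key(raw)
            existing = self._entries.get(key)
            if existing is not None and existing != entry:
                raise DictionaryError(
                    f"conflicting duplicate drug mapping for {raw!r}"
                )
            if entry.atc_code.upper().startswith("N05A"):
                if entry.apd_class is APDClass.NON_APD:
                    raise DictionaryError(
                        f"{entry.generic_name!r} has an N05A ATC code but class non_apd"
                    )
            elif entry.apd_class is not APDClass.NON_APD:
                raise DictionaryError(
                    f"{entry.generic_name!r} is classed {entry.apd_class.value} "
                    f"but its ATC code {entry.atc_code!r} is outside N05A"
                )
            self._entries[key] = entry

    def lookup(self, raw_name: str) -> Optional[DrugEntry]:
        return self._entries.get(normalize_key(raw_name))

    def __len__(self) -> int:
        return len(self._entries)

    def entries(self) -> dict[str, DrugEntry]:
        return dict(self._entries)

    def apd_generics(self) -> dict[str, APDClass]:
        """Distinct antipsychotic generic names and their classes."""
        out: dict[str, APDClass] = {}
        for entry in self._entries.values():
            if entry.apd_class is not APDClass.NON_APD:
                out[entry.generic_name] = entry.apd_class
        return out


@dataclass(frozen=True)
class TermEntry:
    pt: str
    soc: str


class TermDictionary:
    """Raw reaction term -> (preferred term, primary system organ class)."""

    def __init__(self, entries: Mapping[str, TermEntry]):
        self._entries: dict[str, TermEntry] = {}
        pt_to_soc: dict[str, str] = {}
        for raw, entry in entries.items():
            key = normalize_key(raw)
            existing = self._entries.get(key)
            if existing is not None and existing != entry:
                raise DictionaryError(
                    f"conflicting duplicate term mapping for {raw!r}"
                )
            seen_soc = pt_to_soc.get(entry.pt)
            if seen_soc is not None and seen_soc != entry.soc:
                raise DictionaryError(
                    f"preferred term {entry.pt!r} mapped to two primary SOCs: "
                    f"{seen_soc!r} and {entry.soc!r}"
                )
            pt_to_soc[entry.pt] = entry.soc
            self._entries[key] = entry

    def lookup(self, raw_term: str) -> Optional[TermEntry]:
        return self._entries.get(normalize_key(raw_term))

    def __len__(self) -> int:
        return len(self._entries)

    def entries(self) -> dict[str, TermEntry]:
        return dict(self._entries)


class LabelKnowledge:
    """Generic drug name -> set of labeled preferred terms.

    Membership is exact-string on standardized PTs. A drug absent from the
    knowledge base yields no judgement (callers must treat it as
    undetermined, never as labeled).
    """

    def __init__(self, labeled: Mapping[str, Iterable[str]]):
        self._labeled = {drug: frozenset(pts) for drug, pts in labeled.items()}

    def knows(self, generic_name: str) -> bool:
        return generic_name in self._labeled

    def labeled_pts(self, generic_name: str) -> frozenset[str]:
        return self._labeled.get(generic_name, frozenset())

    def drugs(self) -> list[str]:
        return sorted(self._labeled)
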