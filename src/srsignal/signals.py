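"""Fourfold tables and disproportionality statistics for drug-event pairs.

For each (drug, preferred term) pair the combination set is partitioned into
the classic 2x2 table

    =============  ==========  ==========
    ..             target ADR  other ADRs
    =============  ==========  ==========
    target drug        a           b
    other drugs        c           d
    =============  ==========  ==========

with n = a+b+c+d counting drug-event combinations (not reports). Four
methods are computed per pair:

* ROR  = (a/c)/(b/d), Wald 95% CI on the log scale.
* PRR  = [a/(a+b)]/[c/(c+d)], Wald 95% CI on the log scale.
* MHRA = PRR plus a chi-squared statistic (Yates-corrected by default,
  plain Pearson optionally; the Yates numerator is clamped at zero).
* BCPNN information component with shrinkage:
  E(IC) = log2[(a+1)(n+2)^2 / ((n+4)(a+b+1)(a+c+1))],
  V(IC) = (ln 2)^-2 [ (n-a+3)/((a+1)(n+5)) + (n-(a+b)+1)/((a+b+1)(n+3))
                      + (n-(a+c)+1)/((a+c+1)(n+3)) ],
  CI = E(IC) +/- 2 sqrt(V(IC)).

Signal criteria: ROR and PRR flag when a >= 3 and the CI lower limit
exceeds 1; MHRA flags when a >= 3, PRR >= 2 and chi-squared >= 4; BCPNN
flags when the IC lower limit exceeds 0. The consensus flag requires all
four. Tables with a zero cell yield typed non-computable statistics (with a
reason, never infinities) and can never be flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import DrugEventCombination


@dataclass(frozen=True)
class ContingencyTable:
    """Fourfold counts for one drug-event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RatioStats:
    """A point estimate with its 95% CI, or a non-computable marker."""

    value: Optional[float]
    li95: Optional[float]
    ui95: Optional[float]
    reason: Optional[str] = None

    @property
    def computable(self) -> bool:
        return self.reason is None


@dataclass(frozen=True)
class IcStats:
    eic: Optional[float]
    vic: Optional[float]
    li95: Optional[float]
    ui95: Optional[float]
    reason: Optional[str] = None

    @property
    def computable(self) -> bool:
        return self.reason is None


@dataclass(frozen=True)
class SignalConfig:
    """Thresholds and method variants (all overridable, defaults as published)."""

    z: float = 1.96
    min_a: int = 3
    ror_li_threshold: float = 1.0
    prr_li_threshold: float = 1.0
    mhra_prr_threshold: float = 2.0
    mhra_chi2_threshold: float = 4.0
    ic_li_threshold: float = 0.0
    ic_multiplier: float = 2.0
    chi2_variant: str = "yates"  # "yates" | "pearson"
    ic_variant: str = "n4"  # "n4" | "plain"

    def __post_init__(self) -> None:
        if self.chi2_variant not in {"yates", "pearson"}:
            raise ValueError(f"unknown chi2 variant {self.chi2_variant!r}")
        if self.ic_variant not in {"n4", "plain"}:
            raise ValueError(f"unknown IC variant {self.ic_variant!r}")


def build_table(
    combinations: Sequence[DrugEventCombination], drug: str, pt: str
) -> ContingencyTable:
    """Classify every combination into exactly one cell of the fourfold table."""
    a = b = c = d = 0
    for combo in combinations:
        is_drug = combo.generic_drug == drug
        is_pt = combo.pt == pt
        if is_drug and is_pt:
            a += 1
        elif is_drug:
            b += 1
        elif is_pt:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def ror_stats(table: ContingencyTable, z: float = 1.96) -> RatioStats:
    """Reporting odds ratio with log-scale Wald CI; needs all cells positive."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return RatioStats(None, None, None, reason="zero cell")
    ror = (a / c) / (b / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RatioStats(ror, ror * math.exp(-z * se), ror * math.exp(z * se))


def prr_stats(table: ContingencyTable, z: float = 1.96) -> RatioStats:
    """Proportional reporting ratio with log-scale Wald CI."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == 0 or c == 0:
        return RatioStats(None, None, None, reason="zero cell")
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return RatioStats(prr, prr * math.exp(-z * se), prr * math.exp(z * se))


def chi2_stat(table: ContingencyTable, corrected: bool = True) -> tuple[Optional[float], Optional[str]]:
    """Chi-squared on the fourfold table; Yates continuity correction optional.

    The corrected numerator |ad-bc| - n/2 is clamped at zero so exact
    independence scores zero under both variants. All four margins must be
    positive.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return None, "zero margin"
    cross = a * d - b * c
    if corrected:
        num = max(0.0, abs(cross) - n / 2)
    else:
        num = abs(cross)
    return n * num * num / denom, None


def bcpnn_stats(
    table: ContingencyTable, multiplier: float = 2.0, variant: str = "n4"
) -> IcStats:
    """Shrunk information component E(IC), V(IC) and the +/- multiplier*sd CI.

    The "plain" variant drops the (n+2)/(n+4) factor; both shrink to ~0
    under independence.
    """
    a, b, c = table.a, table.b, table.c
    n = table.n
    if n <= 0:
        return IcStats(None, None, None, None, reason="empty table")
    ab = a + b
    ac = a + c
    if variant == "n4":
        ratio = (a + 1) * (n + 2) ** 2 / ((n + 4) * (ab + 1) * (ac + 1))
    elif variant == "plain":
        ratio = (a + 1) * (n + 2) / ((ab + 1) * (ac + 1))
    else:
        raise ValueError(f"unknown IC variant {variant!r}")
    eic = math.log2(ratio)
    vic = (
        (n - a + 3) / ((a + 1) * (n + 5))
        + (n - ab + 1) / ((ab + 1) * (n + 3))
        + (n - ac + 1) / ((ac + 1) * (n + 3))
    ) / math.log(2) ** 2
    sd = math.sqrt(vic)
    return IcStats(eic, vic, eic - multiplier * sd, eic + multiplier * sd)


@dataclass
class SignalResult:
    """All four methods' statistics and flags for one drug-event pair."""

    drug: str
    pt: str
    table: ContingencyTable
    ror: RatioStats
    prr: RatioStats
    chi2: Optional[float]
    chi2_reason: Optional[str]
    ic: IcStats
    flag_ror: bool = False
    flag_prr: bool = False
    flag_mhra: bool = False
    flag_bcpnn: bool = False
    flag_consensus: bool = False
    offlabel: str = "undetermined"  # "labeled" | "off_label" | "undetermined"
    soc: Optional[str] = None


def evaluate_criteria(result: SignalResult, config: SignalConfig = SignalConfig()) -> SignalResult:
    """Set the four per-method flags and the consensus flag in place."""
    a = result.table.a
    result.flag_ror = bool(
        a >= config.min_a
        and result.ror.computable
        and result.ror.li95 > config.ror_li_threshold
    )
    result.flag_prr = bool(
        a >= config.min_a
        and result.prr.computable
        and result.prr.li95 > config.prr_li_threshold
    )
    result.flag_mhra = bool(
        a >= config.min_a
        and result.prr.computable
        and result.prr.value >= config.mhra_prr_threshold
        and result.chi2 is not None
        and result.chi2 >= config.mhra_chi2_threshold
    )
    result.flag_bcpnn = bool(
        result.ic.computable and result.ic.li95 > config.ic_li_threshold
    )
    result.flag_consensus = (
        result.flag_ror and result.flag_prr and result.flag_mhra and result.flag_bcpnn
    )
    return result


def compute_signal(
    table: ContingencyTable,
    drug: str = "",
    pt: str = "",
    config: SignalConfig = SignalConfig(),
) -> SignalResult:
    """Compute all four methods and flags for one fourfold table."""
    chi2, chi2_reason = chi2_stat(table, corrected=config.chi2_variant == "yates")
    result = SignalResult(
        drug=drug,
        pt=pt,
        table=table,
        ror=ror_stats(table, z=config.z),
        prr=prr_stats(table, z=config.z),
        chi2=chi2,
        chi2_reason=chi2_reason,
        ic=bcpnn_stats(table, multiplier=config.ic_multiplier, variant=config.ic_variant),
    )
    return evaluate_criteria(result, config)


def enumerate_tables(
    combinations: Sequence[DrugEventCombination],
) -> dict[tuple[str, str], ContingencyTable]:
    """Fourfold tables for every (drug, PT) pair observed at least once.

    Pairs with a = 0 are structurally uninformative and not enumerated.
    """
    if not combinations:
        return {}
    frame = pd.DataFrame(
        {
            "drug": [c.generic_drug for c in combinations],
            "pt": [c.pt for c in combinations],
        }
    )
    n = len(frame)
    pair_counts = frame.groupby(["drug", "pt"], sort=True).size()
    drug_margin = frame.groupby("drug").size()
    pt_margin = frame.groupby("pt").size()
    tables: dict[tuple[str, str], ContingencyTable] = {}
    for (drug, pt), a in pair_counts.items():
        ab = int(drug_margin[drug])
        ac = int(pt_margin[pt])
        a = int(a)
        tables[(drug, pt)] = ContingencyTable(a, ab - a, ac - a, n - ab - ac + a)
    return tables


def compute_signals(
    combinations: Sequence[DrugEventCombination],
    config: SignalConfig = SignalConfig(),
) -> list[SignalResult]:
    """Evaluate every observed drug-event pair; sorted by (drug, pt)."""
    soc_of: dict[str, str] = {c.pt: c.soc for c in combinations}
    results = []
    for (drug, pt), table in enumerate_tables(combinations).items():
        result = compute_signal(table, drug=drug, pt=pt, config=config)
        result.soc = soc_of.get(pt)
        results.append(result)
    return results


def rank_signals(results: Iterable[SignalResult]) -> list[SignalResult]:
    """Consensus-positive signals sorted by PRR descending.

    Ties break by a descending, then drug name, then PT name, so the order
    is stable across runs.
    """
    positives = [r for r in results if r.flag_consensus]
    return sorted(
        positives,
        key=lambda r: (-r.prr.value, -r.table.a, r.drug, r.pt),
    )


def signals_to_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Flatten signal results to a table mirroring the published layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "drug": r.drug,
                "pt": r.pt,
                "soc": r.soc,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "n": r.table.n,
                "ror": r.ror.value,
                "ror_li95": r.ror.li95,
                "ror_ui95": r.ror.ui95,
                "prr": r.prr.value,
                "prr_li95": r.prr.li95,
                "prr_ui95": r.prr.ui95,
                "chi2": r.chi2,
                "eic": r.ic.eic,
                "vic": r.ic.vic,
                "ic_li95": r.ic.li95,
                "ic_ui95": r.ic.ui95,
                "flag_ror": r.flag_ror,
                "flag_prr": r.flag_prr,
                "flag_mhra": r.flag_mhra,
                "flag_bcpnn": r.flag_bcpnn,
                "flag_consensus": r.flag_consensus,
                "offlabel": r.offlabel,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug", "pt", "soc", "a", "b", "c", "d", "n",
            "ror", "ror_li95", "ror_ui95",
            "prr", "prr_li95", "prr_ui95",
            "chi2", "eic", "vic", "ic_li95", "ic_ui95",
            "flag_ror", "flag_prr", "flag_mhra", "flag_bcpnn", "flag_consensus",
            "offlabel",
        ],
    )


def probe_consistent_tables(
    n: int,
    ror_li95: float,
    prr: float,
    prr_li95: float,
    chi2: float,
    ic_li95: float,
    tol: float = 0.005,
    max_a: int = 80,
    max_row: int = 800,
    max_col: int = 3000,
    config: SignalConfig = SignalConfig(),
) -> list[ContingencyTable]:
    """Diagnostic: integer tables at total n consistent with published statistics.

    Exhaustively searches a (a, row-total, column-total) grid for tables whose
    five statistics match the given values within ``tol`` relative error
    (published values are rounded to 2 dp, so matches are not unique). This is
    a consistency probe, not a reconstruction.
    """
    hits: list[ContingencyTable] = []
    corrected = config.chi2_variant == "yates"
    for a in range(config.min_a, max_a + 1):
        rows = np.arange(a + 1, max_row + 1, dtype=np.float64)
        cols = np.arange(a + 1, max_col + 1, dtype=np.float64)
        ab = rows[:, None]  # row totals
        ac = cols[None, :]  # column totals
        b = ab - a
        c = ac - a
        d = n - ab - ac + a
        valid = d > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            prr_v = (a / ab) / (c / (c + d))
            prr_se = np.sqrt(1 / a - 1 / ab + 1 / c - 1 / (c + d))
            prr_li = prr_v * np.exp(-config.z * prr_se)
            ror_v = (a / c) / (b / d)
            ror_se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            ror_li = ror_v * np.exp(-config.z * ror_se)
            cross = np.abs(a * d - b * c)
            num = np.maximum(0.0, cross - n / 2) if corrected else cross
            chi2_v = n * num**2 / (ab * (n - ab) * ac * (n - ac))
            eic = np.log2((a + 1) * (n + 2) ** 2 / ((n + 4) * (ab + 1) * (ac + 1)))
            vic = (
                (n - a + 3) / ((a + 1) * (n + 5))
                + (n - ab + 1) / ((ab + 1) * (n + 3))
                + (n - ac + 1) / ((ac + 1) * (n + 3))
            ) / math.log(2) ** 2
            ic_li = eic - config.ic_multiplier * np.sqrt(vic)
        ok = (
            valid
            & (np.abs(prr_v - prr) <= tol * abs(prr))
            & (np.abs(prr_li - prr_li95) <= tol * abs(prr_li95))
            & (np.abs(ror_li - ror_li95) <= tol * abs(ror_li95))
            & (np.abs(chi2_v - chi2) <= tol * abs(chi2))
            & (np.abs(ic_li - ic_li95) <= tol * max(abs(ic_li95), 1.0))
        )
        for i, j in zip(*np.nonzero(ok)):
            ab_i = int(rows[i])
            ac_j = int(cols[j])
            hits.append(
                ContingencyTable(a, ab_i - a, ac_j - a, n - ab_i - ac_j + a)
            )
    return hits
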