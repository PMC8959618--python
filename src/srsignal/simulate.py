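"""Synthetic spontaneous-report generator with known ground truth.

The generative model, per report: sample covariates from their marginals,
one suspected antipsychotic from the roster frequency vector, a reaction
count, and each reaction preferred term from the baseline PT vector
multiplicatively reweighted (then renormalized) by the reporting-rate ratio
of any injected (drug, PT) pair. Seriousness is Bernoulli on a logistic
link over the modeled covariates. Onset delays are log-normal. A small
configurable fraction of reports is made excludable on purpose
(out-of-window year, non-antipsychotic suspected drug, rejected causality)
so the inclusion stage has real work to do.

Because injection reweights the conditional PT distribution, expected
fourfold cells have a closed form (:func:`expected_table`), which recovery
tests use as an oracle.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import yaml

from .records import (
    ADRReport,
    APDClass,
    Causality,
    DrugRole,
    DrugUse,
    HospitalType,
    Outcome,
    ReactionRecord,
    Sex,
)

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class DrugSpec:
    name: str
    apd_class: str  # "typical" | "atypical"
    prob: float


@dataclass(frozen=True)
class PtSpec:
    pt: str
    soc: str
    prob: float


@dataclass(frozen=True)
class InjectedPair:
    drug: str
    pt: str
    rr: float  # reporting-rate ratio >= 1


@dataclass
class SyntheticConfig:
    """Full parameterization of the generator. The seed is mandatory at
    generation time, not stored here."""

    n_reports: int
    year_start: int
    year_end: int
    year_probs: dict[int, float]
    drugs: list[DrugSpec]
    pts: list[PtSpec]
    injected_pairs: list[InjectedPair]
    reaction_count_probs: dict[int, float]
    concomitant_pool: list[str]
    concomitant_count_probs: dict[int, float]
    sex_probs: dict[str, float]
    age_bin_probs: dict[str, float]  # "<18", "18-35", "35-65", ">=65"
    age_missing_rate: float
    hospital_level_probs: dict[int, float]
    hospital_type_probs: dict[str, float]
    diagnoses_count_probs: dict[int, float]
    serious_intercept: float
    serious_coefs: dict[str, float]
    onset_log_mu: float
    onset_log_sigma: float
    outcome_probs: dict[str, float]
    causality_probs: dict[str, float]
    out_of_window_rate: float = 0.0
    non_apd_suspected_rate: float = 0.0
    non_apd_suspected_name: str = "off-roster drug"

    def validate(self) -> None:
        def check(vec: Sequence[float], what: str) -> None:
            total = float(sum(vec))
            if abs(total - 1.0) > _PROB_TOL:
                raise ValueError(f"{what} probabilities sum to {total}, not 1")
            if any(p < 0 for p in vec):
                raise ValueError(f"{what} has a negative probability")

        check([d.prob for d in self.drugs], "drug")
        check([p.prob for p in self.pts], "PT")
        check(list(self.year_probs.values()), "year")
        check(list(self.reaction_count_probs.values()), "reaction count")
        check(list(self.concomitant_count_probs.values()), "concomitant count")
        check(list(self.sex_probs.values()), "sex")
        check(list(self.age_bin_probs.values()), "age bin")
        check(list(self.hospital_level_probs.values()), "hospital level")
        check(list(self.hospital_type_probs.values()), "hospital type")
        check(list(self.diagnoses_count_probs.values()), "diagnoses count")
        check(list(self.outcome_probs.values()), "outcome")
        check(list(self.causality_probs.values()), "causality")
        drug_names = {d.name for d in self.drugs}
        pt_names = {p.pt for p in self.pts}
        for pair in self.injected_pairs:
            if pair.rr < 1.0:
                raise ValueError(f"injected rr must be >= 1, got {pair.rr}")
            if pair.drug not in drug_names:
                raise ValueError(f"injected pair references unknown drug {pair.drug!r}")
            if pair.pt not in pt_names:
                raise ValueError(f"injected pair references unknown PT {pair.pt!r}")
        if not 0 <= self.out_of_window_rate < 1:
            raise ValueError("out_of_window_rate must be in [0, 1)")
        if not 0 <= self.non_apd_suspected_rate < 1:
            raise ValueError("non_apd_suspected_rate must be in [0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["drugs"] = [DrugSpec(**d) for d in raw["drugs"]]
        raw["pts"] = [PtSpec(**p) for p in raw["pts"]]
        raw["injected_pairs"] = [InjectedPair(**p) for p in raw["injected_pairs"]]
        for key in (
            "year_probs",
            "reaction_count_probs",
            "concomitant_count_probs",
            "hospital_level_probs",
            "diagnoses_count_probs",
        ):
            raw[key] = {int(k): float(v) for k, v in raw[key].items()}
        return cls(**raw)


@dataclass
class GroundTruth:
    """What the generator injected, for recovery testing."""

    seed: int
    n_reports: int
    injected_pairs: list[InjectedPair]
    serious_intercept: float
    serious_coefs: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "n_reports": self.n_reports,
                    "injected_pairs": [dataclasses.asdict(p) for p in self.injected_pairs],
                    "serious_intercept": self.serious_intercept,
                    "serious_coefs": self.serious_coefs,
                },
                fh,
                indent=2,
            )


_AGE_BIN_RANGES = {"<18": (6.0, 18.0), "18-35": (18.0, 35.0), "35-65": (35.0, 65.0), ">=65": (65.0, 90.0)}
_SEASON_OF_MONTH = np.array(
    ["winter", "winter", "spring", "spring", "spring", "summer",
     "summer", "summer", "autumn", "autumn", "autumn", "winter"]
)


def _reweighted_pt_probs(config: SyntheticConfig, drug: Optional[str]) -> np.ndarray:
    base = np.array([p.prob for p in config.pts], dtype=float)
    if drug is not None:
        for pair in config.injected_pairs:
            if pair.drug == drug:
                idx = next(i for i, p in enumerate(config.pts) if p.pt == pair.pt)
                base[idx] *= pair.rr
    return base / base.sum()


def generate_reports(
    config: SyntheticConfig, seed: int
) -> tuple[list[ADRReport], GroundTruth]:
    """Generate a synthetic dataset; identical seeds give identical datasets."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_reports

    years = np.array(sorted(config.year_probs), dtype=int)
    year = rng.choice(years, size=n, p=[config.year_probs[y] for y in years])
    month = rng.integers(1, 13, size=n)
    day = rng.integers(1, 29, size=n)
    out_of_window = rng.random(n) < config.out_of_window_rate
    year = np.where(out_of_window, config.year_start - 1, year)

    sex_levels = list(config.sex_probs)
    sex = rng.choice(sex_levels, size=n, p=[config.sex_probs[s] for s in sex_levels])
    bin_levels = list(config.age_bin_probs)
    bins = rng.choice(bin_levels, size=n, p=[config.age_bin_probs[b] for b in bin_levels])
    lo = np.array([_AGE_BIN_RANGES[b][0] for b in bins])
    hi = np.array([_AGE_BIN_RANGES[b][1] for b in bins])
    age = np.round(lo + rng.random(n) * (hi - lo), 1)
    age_missing = rng.random(n) < config.age_missing_rate

    levels = np.array(sorted(config.hospital_level_probs), dtype=int)
    level = rng.choice(levels, size=n, p=[config.hospital_level_probs[l] for l in levels])
    type_levels = list(config.hospital_type_probs)
    htype = rng.choice(
        type_levels, size=n, p=[config.hospital_type_probs[t] for t in type_levels]
    )
    diag_counts = np.array(sorted(config.diagnoses_count_probs), dtype=int)
    n_diag = rng.choice(
        diag_counts, size=n, p=[config.diagnoses_count_probs[k] for k in diag_counts]
    )

    drug_idx = rng.choice(
        len(config.drugs), size=n, p=[d.prob for d in config.drugs]
    )
    non_apd = rng.random(n) < config.non_apd_suspected_rate

    conc_counts = np.array(sorted(config.concomitant_count_probs), dtype=int)
    n_conc = rng.choice(
        conc_counts, size=n, p=[config.concomitant_count_probs[k] for k in conc_counts]
    )

    k_levels = np.array(sorted(config.reaction_count_probs), dtype=int)
    n_react = rng.choice(
        k_levels, size=n, p=[config.reaction_count_probs[k] for k in k_levels]
    )

    # PT draws, grouped by suspected drug so the injected reweighting applies.
    pt_idx_per_report: list[np.ndarray] = [np.empty(0, dtype=int)] * n
    n_pts = len(config.pts)
    for d in range(len(config.drugs)):
        members = np.nonzero((drug_idx == d) & ~non_apd)[0]
        if members.size == 0:
            continue
        q = _reweighted_pt_probs(config, config.drugs[d].name)
        ks = n_react[members]
        draws = rng.choice(n_pts, size=int(ks.sum()), p=q)
        offsets = np.concatenate([[0], np.cumsum(ks)])
        for j, report_i in enumerate(members):
            pt_idx_per_report[report_i] = draws[offsets[j]:offsets[j + 1]]
    members = np.nonzero(non_apd)[0]
    if members.size:
        q = _reweighted_pt_probs(config, None)
        ks = n_react[members]
        draws = rng.choice(n_pts, size=int(ks.sum()), p=q)
        offsets = np.concatenate([[0], np.cumsum(ks)])
        for j, report_i in enumerate(members):
            pt_idx_per_report[report_i] = draws[offsets[j]:offsets[j + 1]]

    react_offsets = np.concatenate([[0], np.cumsum(n_react)])
    all_delays = np.maximum(
        0,
        np.round(
            rng.lognormal(
                config.onset_log_mu, config.onset_log_sigma, size=int(n_react.sum())
            )
        ),
    ).astype(int)
    max_delay = np.maximum.reduceat(all_delays, react_offsets[:-1])

    # Seriousness via the logistic link; must mirror the risk-factor encoding.
    coefs = config.serious_coefs
    drug_is_atypical = np.array(
        [config.drugs[d].apd_class == "atypical" for d in drug_idx]
    )
    season = _SEASON_OF_MONTH[month - 1]
    lp = np.full(n, config.serious_intercept)
    lp += coefs.get("female", 0.0) * (sex == "female")
    lp += coefs.get("age_lt18", 0.0) * (bins == "<18")
    lp += coefs.get("age_35_65", 0.0) * (bins == "35-65")
    lp += coefs.get("age_ge65", 0.0) * (bins == ">=65")
    lp += coefs.get("summer", 0.0) * (season == "summer")
    lp += coefs.get("autumn", 0.0) * (season == "autumn")
    lp += coefs.get("winter", 0.0) * (season == "winter")
    lp += coefs.get("atypical", 0.0) * drug_is_atypical
    lp += coefs.get("level2", 0.0) * (level == 2)
    lp += coefs.get("level3", 0.0) * (level == 3)
    lp += coefs.get("psychiatric", 0.0) * (htype == "psychiatric")
    lp += coefs.get("multiple_disease", 0.0) * (n_diag >= 2)
    lp += coefs.get("polypharmacy", 0.0) * ((1 + n_conc) >= 3)
    serious = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))

    outcome_levels = list(config.outcome_probs)
    outcome = rng.choice(
        outcome_levels, size=n, p=[config.outcome_probs[o] for o in outcome_levels]
    )
    causality_levels = list(config.causality_probs)
    causality = rng.choice(
        causality_levels, size=n, p=[config.causality_probs[c] for c in causality_levels]
    )
    conc_names = rng.choice(config.concomitant_pool, size=int(n_conc.sum()))
    conc_offsets = np.concatenate([[0], np.cumsum(n_conc)])

    reports: list[ADRReport] = []
    pt_names = [p.pt for p in config.pts]
    from_ordinal = datetime.date.fromordinal
    report_ordinal = np.array(
        [
            datetime.date(y, m, d).toordinal()
            for y, m, d in zip(year.tolist(), month.tolist(), day.tolist())
        ],
        dtype=np.int64,
    )
    start_ordinal = (report_ordinal - max_delay).tolist()
    onset_ordinal = (np.repeat(report_ordinal - max_delay, n_react) + all_delays).tolist()
    report_ordinal = report_ordinal.tolist()
    sex_enum = [Sex(s) for s in sex.tolist()]
    htype_enum = [HospitalType(t) for t in htype.tolist()]
    causality_enum = [Causality(c) for c in causality.tolist()]
    outcome_enum = [Outcome(o) for o in outcome.tolist()]
    age_values = age.tolist()
    age_missing = age_missing.tolist()
    level_values = level.tolist()
    n_diag_values = n_diag.tolist()
    serious_values = serious.tolist()
    non_apd_values = non_apd.tolist()
    drug_names_by_idx = [d.name for d in config.drugs]
    conc_names = conc_names.tolist()
    diagnoses_of = {
        k: [f"diagnosis {j + 1}" for j in range(k)]
        for k in config.diagnoses_count_probs
    }
    for i in range(n):
        start = from_ordinal(start_ordinal[i])
        drug_name = (
            config.non_apd_suspected_name
            if non_apd_values[i]
            else drug_names_by_idx[drug_idx[i]]
        )
        drugs = [DrugUse(raw_name=drug_name, role=DrugRole.SUSPECTED, start_date=start)]
        for j in range(conc_offsets[i], conc_offsets[i + 1]):
            drugs.append(DrugUse(raw_name=conc_names[j], role=DrugRole.CONCOMITANT))
        lo_r, hi_r = react_offsets[i], react_offsets[i + 1]
        reactions = [
            ReactionRecord(
                raw_term=pt_names[pt_idx],
                onset_date=from_ordinal(onset_ordinal[j]),
            )
            for pt_idx, j in zip(pt_idx_per_report[i], range(lo_r, hi_r))
        ]
        reports.append(
            ADRReport(
                report_id=f"R{i:06d}",
                sex=sex_enum[i],
                age=None if age_missing[i] else age_values[i],
                report_date=from_ordinal(report_ordinal[i]),
                hospital_level=level_values[i],
                hospital_type=htype_enum[i],
                diagnoses=list(diagnoses_of.get(n_diag_values[i], [])),
                drugs=drugs,
                reactions=reactions,
                causality=causality_enum[i],
                serious=serious_values[i],
                outcome=outcome_enum[i],
            )
        )
    truth = GroundTruth(
        seed=seed,
        n_reports=n,
        injected_pairs=list(config.injected_pairs),
        serious_intercept=config.serious_intercept,
        serious_coefs=dict(config.serious_coefs),
    )
    return reports, truth


@dataclass(frozen=True)
class ExpectedTable:
    """Analytic expected fourfold cells under the generative model."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


def _inclusion_probability(config: SyntheticConfig) -> float:
    p_accept = sum(
        config.causality_probs.get(c, 0.0) for c in ("certain", "probable", "possible")
    )
    return (
        (1.0 - config.out_of_window_rate)
        * (1.0 - config.non_apd_suspected_rate)
        * p_accept
    )


def _expected_distinct(config: SyntheticConfig, q: np.ndarray) -> np.ndarray:
    """E[PT j appears at least once among the report's reactions], per j."""
    out = np.zeros_like(q)
    for k, pk in config.reaction_count_probs.items():
        out += pk * (1.0 - (1.0 - q) ** k)
    return out


def expected_table(config: SyntheticConfig, drug: str, pt: str) -> ExpectedTable:
    """Closed-form expected fourfold table for (drug, pt) after inclusion
    filtering, in combination units. Linear in n_reports."""
    drug_names = [d.name for d in config.drugs]
    pt_names = [p.pt for p in config.pts]
    if drug not in drug_names:
        raise ValueError(f"unknown drug {drug!r}")
    if pt not in pt_names:
        raise ValueError(f"unknown PT {pt!r}")
    x = pt_names.index(pt)
    n_included = config.n_reports * _inclusion_probability(config)

    a = row = col = total = 0.0
    for spec in config.drugs:
        q = _reweighted_pt_probs(config, spec.name)
        e = _expected_distinct(config, q)
        weight = n_included * spec.prob
        total += weight * e.sum()
        col += weight * e[x]
        if spec.name == drug:
            a = weight * e[x]
            row = weight * e.sum()
    return ExpectedTable(a=a, b=row - a, c=col - a, d=total - row - col + a)


def expected_serious_fraction(
    config: SyntheticConfig, n_draws: int = 50_000, seed: int = 0
) -> float:
    """Monte-Carlo mean of the seriousness probability under the config."""
    cfg = dataclasses.replace(config, n_reports=n_draws)
    reports, _ = generate_reports(cfg, seed=seed)
    return float(np.mean([r.serious for r in reports]))


def paperlike_config(n_reports: int = 50_000) -> SyntheticConfig:
    """Default configuration echoing the study's regime: a 15-drug roster with
    report-count-proportional frequencies, a 40-PT vocabulary, ~9% serious
    reports, ~1.19 reactions per report, and eight injected signal pairs."""
    drug_counts = {
        # atypical
        "risperidone": (1083, "atypical"),
        "clozapine": (554, "atypical"),
        "olanzapine": (350, "atypical"),
        "aripiprazole": (236, "atypical"),
        "quetiapine": (214, "atypical"),
        "amisulpride": (207, "atypical"),
        "ziprasidone": (206, "atypical"),
        "perospirone": (120, "atypical"),
        # typical
        "haloperidol": (216, "typical"),
        "perphenazine": (64, "typical"),
        "sulpiride": (61, "typical"),
        "chlorpromazine": (43, "typical"),
        "penfluridol": (5, "typical"),
        "chlorprothixene": (3, "typical"),
        "droperidol": (1, "typical"),
    }
    total = sum(c for c, _ in drug_counts.values())
    drugs = [
        DrugSpec(name=name, apd_class=cls, prob=count / total)
        for name, (count, cls) in drug_counts.items()
    ]

    pt_masses = [
        ("Extrapyramidal disorder", "Nervous system disorders", 0.240),
        ("Akathisia", "Nervous system disorders", 0.060),
        ("Constipation", "Gastrointestinal disorders", 0.050),
        ("Drooling", "Gastrointestinal disorders", 0.040),
        ("White blood cell count decreased", "Investigations", 0.038),
        ("Tremor", "Nervous system disorders", 0.031),
        ("Somnolence", "Nervous system disorders", 0.021),
        ("Hepatic function abnormal", "Hepatobiliary disorders", 0.020),
        ("Dizziness", "Nervous system disorders", 0.020),
        ("Tachycardia", "Cardiac disorders", 0.019),
        ("Dystonia", "Nervous system disorders", 0.015),
        ("Insomnia", "Psychiatric disorders", 0.008),
        ("Orthostatic hypotension", "Vascular disorders", 0.006),
        ("Tongue induration", "Gastrointestinal disorders", 0.003),
        ("Blood pressure decreased", "Investigations", 0.005),
        ("Pruritus", "Skin and subcutaneous tissue disorders", 0.005),
        ("Obesity", "Metabolism and nutrition disorders", 0.004),
        ("Pollakiuria", "Renal and urinary disorders", 0.004),
        ("Rash", "Skin and subcutaneous tissue disorders", 0.006),
        ("Nuchal rigidity", "Musculoskeletal and connective tissue disorders", 0.003),
        ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.004),
        ("Urinary incontinence", "Renal and urinary disorders", 0.004),
        ("Weight increased", "Investigations", 0.020),
        ("Nausea", "Gastrointestinal disorders", 0.030),
        ("Vomiting", "Gastrointestinal disorders", 0.025),
        ("Palpitations", "Cardiac disorders", 0.015),
        ("Electrocardiogram QT prolonged", "Investigations", 0.015),
        ("Sinus bradycardia", "Cardiac disorders", 0.008),
        ("Hyperprolactinaemia", "Endocrine disorders", 0.010),
        ("Pyrexia", "General disorders and administration site conditions", 0.010),
        ("Fatigue", "General disorders and administration site conditions", 0.010),
        ("Vision blurred", "Eye disorders", 0.008),
        ("Amenorrhoea", "Reproductive system and breast disorders", 0.006),
        ("Galactorrhoea", "Reproductive system and breast disorders", 0.005),
        ("Headache", "Nervous system disorders", 0.020),
        ("Agitation", "Psychiatric disorders", 0.010),
        ("Blood glucose increased", "Investigations", 0.010),
        ("Dry mouth", "Gastrointestinal disorders", 0.012),
        ("Abnormal sensation in eye", "Eye disorders", 0.005),
        ("Hypertonia", "Nervous system disorders", 0.008),
    ]
    mass_total = sum(m for _, _, m in pt_masses)
    pts = [PtSpec(pt=p, soc=s, prob=m / mass_total) for p, s, m in pt_masses]

    injected = [
        InjectedPair("sulpiride", "Insomnia", 5.0),
        InjectedPair("chlorpromazine", "Orthostatic hypotension", 6.0),
        InjectedPair("haloperidol", "Dystonia", 4.5),
        InjectedPair("perphenazine", "Tongue induration", 8.0),
        InjectedPair("olanzapine", "Hepatic function abnormal", 4.0),
        InjectedPair("quetiapine", "Urinary incontinence", 5.0),
        InjectedPair("amisulpride", "Pollakiuria", 5.0),
        InjectedPair("ziprasidone", "Dyspnoea", 4.0),
        # deliberately weak / tiny pairs, below the recovery guarantee
        InjectedPair("perospirone", "Pyrexia", 2.0),
        InjectedPair("droperidol", "Rash", 6.0),
    ]

    # Log odds-ratio effects; intercept tuned so the serious fraction is ~9%.
    or_effects = {
        "female": 1.25,
        "age_lt18": 1.59,
        "age_35_65": 0.98,
        "age_ge65": 2.17,
        "summer": 0.95,
        "autumn": 1.26,
        "winter": 1.31,
        "atypical": 1.55,
        "level2": 0.41,
        "level3": 0.37,
        "psychiatric": 2.61,
        "multiple_disease": 1.67,
        "polypharmacy": 0.92,
    }
    return SyntheticConfig(
        n_reports=n_reports,
        year_start=2016,
        year_end=2020,
        year_probs={2016: 0.12, 2017: 0.16, 2018: 0.20, 2019: 0.24, 2020: 0.28},
        drugs=drugs,
        pts=pts,
        injected_pairs=injected,
        reaction_count_probs={1: 0.85, 2: 0.12, 3: 0.02, 4: 0.007, 5: 0.003},
        concomitant_pool=["benzhexol", "vitamin B1", "aspirin", "metformin"],
        concomitant_count_probs={0: 0.55, 1: 0.25, 2: 0.20},
        sex_probs={"male": 0.515, "female": 0.475, "unknown": 0.01},
        age_bin_probs={"<18": 0.15, "18-35": 0.45, "35-65": 0.33, ">=65": 0.07},
        age_missing_rate=0.02,
        hospital_level_probs={1: 0.20, 2: 0.45, 3: 0.35},
        hospital_type_probs={"psychiatric": 0.60, "general": 0.40},
        diagnoses_count_probs={1: 0.90, 2: 0.10},
        serious_intercept=-3.08,
        serious_coefs={k: float(np.log(v)) for k, v in or_effects.items()},
        onset_log_mu=3.0,
        onset_log_sigma=1.0,
        outcome_probs={
            "relieved": 0.1745,
            "cured": 0.7710,
            "not_relieved": 0.0217,
            "sequelae": 0.0003,
            "missing": 0.0325,
        },
        causality_probs={
            "certain": 0.10,
            "probable": 0.50,
            "possible": 0.37,
            "unlikely": 0.02,
            "impossible": 0.01,
        },
        out_of_window_rate=0.02,
        non_apd_suspected_rate=0.01,
        non_apd_suspected_name="amantadine",
    )
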