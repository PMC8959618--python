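import datetime

import pytest

from srsignal.fixtures import (
    bundled_drug_dictionary,
    bundled_label_knowledge,
    bundled_term_dictionary,
)
from srsignal.preprocess import Covariates, DrugEventCombination, Season
from srsignal.records import (
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


@pytest.fixture(scope="session")
def drug_dict():
    return bundled_drug_dictionary()


@pytest.fixture(scope="session")
def term_dict():
    return bundled_term_dictionary()


@pytest.fixture(scope="session")
def labels():
    return bundled_label_knowledge()


def make_report(
    report_id="R1",
    suspected=("risperidone",),
    concomitant=(),
    reactions=("Extrapyramidal disorder",),
    year=2018,
    month=6,
    day=15,
    sex=Sex.MALE,
    age=30.0,
    hospital_level=2,
    hospital_type=HospitalType.PSYCHIATRIC,
    diagnoses=("schizophrenia",),
    causality=Causality.PROBABLE,
    serious=False,
    outcome=Outcome.CURED,
    start_date=None,
    onset_dates=None,
):
    """Small-report builder shared across the suite."""
    date = datetime.date(year, month, day)
    drugs = [
        DrugUse(raw_name=name, role=DrugRole.SUSPECTED, start_date=start_date)
        for name in suspected
    ]
    drugs += [DrugUse(raw_name=name, role=DrugRole.CONCOMITANT) for name in concomitant]
    if onset_dates is None:
        onset_dates = [None] * len(reactions)
    rx = [
        ReactionRecord(raw_term=term, onset_date=onset)
        for term, onset in zip(reactions, onset_dates)
    ]
    return ADRReport(
        report_id=report_id,
        sex=sex,
        age=age,
        report_date=date,
        hospital_level=hospital_level,
        hospital_type=hospital_type,
        diagnoses=list(diagnoses),
        drugs=drugs,
        reactions=rx,
        causality=causality,
        serious=serious,
        outcome=outcome,
    )


_DEFAULT_COV = Covariates(
    sex=Sex.MALE,
    age=30.0,
    age_bin="18-35",
    year=2018,
    season=Season.SUMMER,
    hospital_level=2,
    hospital_type="psychiatric",
    polypharmacy=False,
    multiple_disease=False,
    apd_class=APDClass.ATYPICAL,
)


def make_combo(report_id, drug, pt, soc="Nervous system disorders",
               apd_class=APDClass.ATYPICAL, serious=False):
    return DrugEventCombination(
        report_id=report_id,
        generic_drug=drug,
        apd_class=apd_class,
        pt=pt,
        soc=soc,
        serious=serious,
        covariates=_DEFAULT_COV,
    )
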