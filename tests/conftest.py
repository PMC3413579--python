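import datetime as dt

import pytest

from linkenhance.records import (
    DeathRecord,
    LinkedRecord,
    Remoteness,
    Sex,
    Source,
    TriState,
)


def make_death(
    death_id="d1",
    age_years=60,
    sex=Sex.MALE,
    remoteness=Remoteness.MAJOR_CITIES,
    cause_icd10="I21",
    reported_indigenous=TriState.NO,
):
    return DeathRecord(death_id, age_years, sex, remoteness, cause_icd10, reported_indigenous)


def make_apd(
    record_id,
    death_id="d1",
    admit="2006-01-03",
    discharge="2006-01-07",
    flag=TriState.NO,
    facility="FA",
    transferred_from=None,
    transferred_to=None,
):
    return LinkedRecord(
        record_id=record_id,
        death_id=death_id,
        source=Source.APD,
        indigenous_flag=flag,
        admit_date=dt.date.fromisoformat(admit),
        discharge_date=dt.date.fromisoformat(discharge),
        facility=facility,
        transferred_from=transferred_from,
        transferred_to=transferred_to,
    )


def make_record(record_id, death_id="d1", source=Source.EDDC, flag=TriState.NO, **kwargs):
    return LinkedRecord(
        record_id=record_id, death_id=death_id, source=source, indigenous_flag=flag, **kwargs
    )


@pytest.fixture
def sample_deaths():
    return [
        make_death("d1", 63, Sex.MALE, Remoteness.MAJOR_CITIES, "I21.4", TriState.YES),
        make_death("d2", 45, Sex.FEMALE, Remoteness.REMOTE, "C50", TriState.NO),
        make_death("d3", 0, Sex.MALE, Remoteness.UNKNOWN, "X42", TriState.MISSING),
    ]


@pytest.fixture
def sample_linked():
    return [
        make_apd("r1", "d2", "2006-01-03", "2006-01-07", TriState.YES, "FA", transferred_to="FB"),
        make_apd("r2", "d2", "2006-01-07", "2006-01-12", TriState.NO, "FB", transferred_from="FA"),
        make_record("r3", "d2", Source.EDDC, TriState.NO),
        make_record(
            "r4",
            "d3",
            Source.PDC_INFANT,
            TriState.NO,
            mother_indigenous_flag=TriState.YES,
        ),
    ]
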