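import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from faerspv.io import (DemoRecord, DrugRecord, DrugRole, Occupation,
                        OutcRecord, ReacRecord, Sex)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_demo(report_id="R1", case_id=None, version=1, received=None,
              event=None, age=None, sex=Sex.UNKNOWN,
              occupation=Occupation.UNKNOWN, country=None) -> DemoRecord:
    return DemoRecord(
        report_id=report_id,
        case_id=case_id or report_id,
        case_version=version,
        received_date=received,
        event_date=event,
        received_raw="" if received is None else received.strftime("%Y%m%d"),
        event_raw="" if event is None else event.strftime("%Y%m%d"),
        age_value=age,
        age_unit="YR" if age is not None else None,
        sex=sex,
        occupation=occupation,
        country=country,
    )


def make_drug(report_id="R1", name="VORAPAXAR", role=DrugRole.PRIMARY_SUSPECT,
              seq=1, ingredient=None, start=None) -> DrugRecord:
    return DrugRecord(
        report_id=report_id, drug_seq=seq, role=role, verbatim_name=name,
        active_ingredient=ingredient, therapy_start_date=start,
        therapy_start_raw="" if start is None else start.strftime("%Y%m%d"),
    )


def make_reac(report_id="R1", pt="PT_A") -> ReacRecord:
    return ReacRecord(report_id=report_id, pt=pt)


def make_outc(report_id="R1", code="HO") -> OutcRecord:
    return OutcRecord(report_id=report_id, outcome_code=code)


@pytest.fixture
def day():
    return lambda offset: dt.date(2015, 1, 1) + dt.timedelta(days=offset)
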