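"""Shared fixtures and record builders for the test suite."""
from __future__ import annotations

from datetime import date

import pytest

from smmsurv.codebook import IcdCode, ProcedureCode, default_codebook
from smmsurv.episodes import EpisodeOfCare, assemble_episodes
from smmsurv.records import (PRIVATE, PUBLIC, AdmissionRecord,
                             DischargeOutcome)

ALIVE = DischargeOutcome.DISCHARGE_ALIVE
DEATH = DischargeOutcome.DEATH
STAY = DischargeOutcome.STAY
TRANSFER = DischargeOutcome.TRANSFER


def make_record(
    schema: str = PUBLIC,
    form_id: str = "A1",
    person: str | None = "P1",
    hospital: str | None = "H1",
    adm: str = "2020-03-01",
    dis: str = "2020-03-04",
    icds: tuple[str, ...] = (),
    procs: tuple[str, ...] = (),
    icu: int = 0,
    outcome: DischargeOutcome = ALIVE,
    hosp_type: str | None = None,
) -> AdmissionRecord:
    """Compact admission-record builder for hand cohorts.

    ICDs land in consecutive diagnosis fields of the schema; procedures use
    the schema's terminology.
    """
    if schema == PUBLIC:
        fields = ["principal"] + [f"secondary_{i}" for i in range(1, 10)] + \
            ["icd_notification", "icd_death", "icd_associated"]
        term = "SIGTAP"
    else:
        fields = [f"icd_{i}" for i in range(1, 5)]
        term = "TUSS"
        person = hospital = None
    diagnoses = tuple(
        (fname, IcdCode.parse(code)) for fname, code in zip(fields, icds))
    return AdmissionRecord(
        schema=schema,
        form_id=form_id,
        person_key=person,
        hospital_key=hospital,
        admission_date=date.fromisoformat(adm),
        discharge_date=date.fromisoformat(dis),
        diagnoses=diagnoses,
        procedures=tuple(ProcedureCode.parse(p, term) for p in procs),
        icu_days=icu,
        discharge_reason=outcome,
        type_of_hospitalization=hosp_type,
    )


def make_episode(**kwargs) -> EpisodeOfCare:
    """Singleton episode wrapping one built record."""
    rec = make_record(**kwargs)
    return assemble_episodes([rec])[0]


@pytest.fixture(scope="session")
def cb():
    return default_codebook()
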