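import datetime as dt

import pytest

from ckdmbd import (
    CalcificationAssessment,
    Encounter,
    LabPanel,
    Prescription,
    load_knowledge_base,
)


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()


def make_encounter(
    mrn="P1",
    seq=1,
    pth=200.0,
    phosphate=4.5,
    total_calcium=9.0,
    albumin=4.0,
    vascular_score=2,
    valvular=False,
    rx=None,
    **rx_doses,
):
    """Build an encounter with in-range defaults (type-II patient)."""
    prescription = rx if rx is not None else Prescription(**rx_doses)
    return Encounter(
        mrn=mrn,
        sequence_index=seq,
        labs=LabPanel(
            encounter_date=dt.date(2021, 1, 1) + dt.timedelta(days=30 * (seq - 1)),
            pth=pth,
            phosphate=phosphate,
            total_calcium=total_calcium,
            albumin=albumin,
        ),
        calcification=CalcificationAssessment(
            vascular_score=vascular_score, valvular_present=valvular
        ),
        prescription=prescription,
    )


@pytest.fixture()
def encounter_factory():
    return make_encounter
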