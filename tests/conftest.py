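import hypothesis
import pytest

from cbcscore import (
    CbcParameter,
    Measurement,
    PatientRecord,
    default_reference_panel,
)

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("ci")

PARAMS = list(CbcParameter)


@pytest.fixture(scope="session")
def panel():
    return default_reference_panel()


def make_record(
    patient_id="P1",
    survival_days=10,
    neu=None,
    lym=None,
    rbc=None,
    hb=None,
    plt=None,
):
    """Build a PatientRecord from keyword CBC values (None = missing)."""
    values = {
        CbcParameter.NEU: neu,
        CbcParameter.LYM: lym,
        CbcParameter.RBC: rbc,
        CbcParameter.HB: hb,
        CbcParameter.PLT: plt,
    }
    return PatientRecord(
        patient_id=patient_id,
        survival_days=survival_days,
        measurements={p: Measurement(p, v) for p, v in values.items()},
    )


@pytest.fixture
def record_at_reference_means(panel):
    """A patient whose every CBC value sits exactly at the reference mean."""
    return make_record(
        patient_id="REF",
        neu=3.5,
        lym=2.2,
        rbc=4.5,
        hb=142.0,
        plt=210.0,
    )
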