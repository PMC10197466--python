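import pytest
from hypothesis import HealthCheck, settings

from mgscreen.rules import PatientRecord, ReferenceRanges

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ranges() -> ReferenceRanges:
    return ReferenceRanges()


@pytest.fixture
def normal_record() -> PatientRecord:
    """A patient with every analyte at the midpoint of its reference range."""
    return PatientRecord(
        id="p0",
        sex="male",
        age=60,
        ca=9.5,
        cr=0.7,
        egfr=90.0,
        hb=15.0,
        tp=7.6,
        igg=11.0,
        iga=2.3,
        igm=1.3,
        bone_involvement=False,
        requested_tests=frozenset({"SPEP"}),
    )
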