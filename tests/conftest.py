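import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from limbscreen import (
    DuplexFinding,
    ParticipantRecord,
    PressurePanel,
    RiskProfile,
    Sex,
    Side,
    Waveform,
    WaveformPanel,
)


def make_record(
    rid="P1",
    age=70,
    sex=Sex.MALE,
    diabetes=False,
    renal=False,
    smoker=False,
    leg_pain=False,
    brachial=(130.0, 125.0),
    ankle_left=(130.0, 120.0),
    ankle_right=(130.0, 120.0),
    toe=(80.0, 80.0),
    duplex=(),
    duplex_same_day=True,
):
    """A fully populated participant record with overridable parts."""
    return ParticipantRecord(
        id=rid,
        risk=RiskProfile(age, sex, diabetes, renal, smoker, leg_pain),
        pressures=PressurePanel(
            brachial_left=brachial[0],
            brachial_right=brachial[1],
            ankle_dp_left=ankle_left[0],
            ankle_pt_left=ankle_left[1],
            ankle_dp_right=ankle_right[0],
            ankle_pt_right=ankle_right[1],
            toe_left=toe[0],
            toe_right=toe[1],
        ),
        waveforms=WaveformPanel(
            Waveform.TRIPHASIC, Waveform.TRIPHASIC, Waveform.TRIPHASIC, Waveform.TRIPHASIC
        ),
        duplex=list(duplex),
        duplex_same_day=duplex_same_day,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def stenosed():
    """One distal segment above the PAD threshold."""
    return DuplexFinding("posterior_tibial", 60.0, False, Side.LEFT)
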