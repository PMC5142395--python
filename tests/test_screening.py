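"""Eligibility, targeted test selection, and both screening strategies."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from limbscreen import (
    INCOMPRESSIBLE,
    Call,
    IndexKind,
    PressurePanel,
    RiskProfile,
    Sex,
    Strategy,
    Thresholds,
    apply_aha,
    apply_targeted,
    check_eligibility,
    screen_cohort,
    select_targeted_test,
)
from conftest import make_record


def risk(age=70, diabetes=False, renal=False, smoker=False, pain=False):
    return RiskProfile(age, Sex.FEMALE, diabetes, renal, smoker, pain)


@pytest.mark.parametrize(
    "kwargs, eligible",
    [
        (dict(age=66), True),                       # over 65 alone
        (dict(age=65), False),                      # boundary is strict
        (dict(age=55, smoker=True), True),          # over 50 + smoking
        (dict(age=55, diabetes=True), True),        # over 50 + diabetes
        (dict(age=50, diabetes=True), False),       # "above 50" is strict
        (dict(age=40, pain=True), True),            # leg pain at any age
        (dict(age=55), False),                      # no qualifying factor
    ],
)
def test_eligibility_rule(kwargs, eligible):
    assert check_eligibility(risk(**kwargs)) is eligible


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        (dict(age=80), IndexKind.TBI),              # advanced age alone
        (dict(age=60, diabetes=True), IndexKind.TBI),
        (dict(age=60, renal=True), IndexKind.TBI),
        (dict(age=75), IndexKind.ABI),              # cutoff is strictly over 75
        (dict(age=76), IndexKind.TBI),
        (dict(age=70, smoker=True, pain=True), IndexKind.ABI),  # other factors -> ABI
    ],
)
def test_targeted_test_selector(kwargs, expected):
    assert select_targeted_test(risk(**kwargs)) is expected


def test_targeted_diabetic_low_tbi_calls_pad():
    rec = make_record(diabetes=True, brachial=(125.0, 120.0), toe=(50.0, 50.0))
    d = apply_targeted(rec)
    assert d.test_used is IndexKind.TBI
    assert d.index_value == pytest.approx(0.40)
    assert d.call is Call.PAD


def test_targeted_nondiabetic_normal_abi_calls_no_pad():
    rec = make_record(age=70, brachial=(120.0, 118.0), ankle_left=(126.0, 120.0), ankle_right=(130.0, 125.0))
    d = apply_targeted(rec)
    assert d.test_used is IndexKind.ABI and d.call is Call.NO_PAD


def test_targeted_missing_toe_excludes_when_tbi_required():
    rec = make_record(diabetes=True, toe=(None, None))
    d = apply_targeted(rec)
    assert d.excluded and d.call is None and "toe" in d.reason


def test_targeted_incompressible_abi_falls_through_to_tbi():
    rec = make_record(
        age=70,
        ankle_left=(INCOMPRESSIBLE, INCOMPRESSIBLE),
        ankle_right=(INCOMPRESSIBLE, INCOMPRESSIBLE),
        brachial=(120.0, 120.0),
        toe=(60.0, 60.0),
    )
    d = apply_targeted(rec)
    assert d.test_used is IndexKind.TBI and d.call is Call.PAD
    # and indeterminate when the rescue TBI is missing too
    rec2 = make_record(
        age=70,
        ankle_left=(INCOMPRESSIBLE, INCOMPRESSIBLE),
        ankle_right=(INCOMPRESSIBLE, INCOMPRESSIBLE),
        toe=(None, None),
    )
    d2 = apply_targeted(rec2)
    assert d2.call is Call.INDETERMINATE and not d2.excluded


def test_aha_substitutes_tbi_above_ceiling():
    rec = make_record(
        brachial=(100.0, 100.0),
        ankle_left=(150.0, 150.0), ankle_right=(150.0, 150.0),
        toe=(55.0, 55.0),
    )
    d = apply_aha(rec)
    assert d.test_used is IndexKind.TBI and d.call is Call.PAD


def test_aha_boundary_abi_exactly_1_4_stays_abi():
    rec = make_record(brachial=(100.0, 100.0), ankle_left=(140.0, 140.0), ankle_right=(140.0, 140.0))
    d = apply_aha(rec)
    assert d.test_used is IndexKind.ABI
    assert d.index_value == pytest.approx(1.40)
    assert d.call is Call.NO_PAD


def test_aha_low_abi_calls_pad_and_boundary_0_9_does_not():
    rec = make_record(brachial=(100.0, 100.0), ankle_left=(80.0, 80.0), ankle_right=(95.0, 95.0))
    assert apply_aha(rec).call is Call.PAD
    rec2 = make_record(brachial=(100.0, 100.0), ankle_left=(90.0, 90.0), ankle_right=(95.0, 95.0))
    d2 = apply_aha(rec2)
    assert d2.index_value == pytest.approx(0.90) and d2.call is Call.NO_PAD


def test_aha_incompressible_fallthrough_is_switchable():
    rec = make_record(
        ankle_left=(INCOMPRESSIBLE, INCOMPRESSIBLE),
        ankle_right=(INCOMPRESSIBLE, INCOMPRESSIBLE),
        toe=(50.0, 50.0),
        brachial=(100.0, 100.0),
    )
    assert apply_aha(rec).call is Call.PAD
    off = Thresholds(aha_incompressible_to_tbi=False)
    assert apply_aha(rec, off).call is Call.INDETERMINATE


def test_aha_never_uses_tbi_for_compressible_in_range_abi():
    for ankle in (60.0, 90.0, 120.0, 140.0):
        rec = make_record(
            brachial=(100.0, 100.0),
            ankle_left=(ankle, ankle), ankle_right=(ankle, ankle),
            toe=(40.0, 40.0),
        )
        assert apply_aha(rec).test_used is IndexKind.ABI


def test_targeted_and_aha_agree_on_abi_path_in_gray_zone():
    # numeric ABI in (abi_lower, abi_upper], no comorbidity -> both use ABI
    rec = make_record(age=70, brachial=(100.0, 100.0), ankle_left=(105.0, 100.0), ankle_right=(110.0, 100.0))
    assert apply_targeted(rec).call == apply_aha(rec).call == Call.NO_PAD


@given(tbi_lower=st.floats(0.35, 0.95), toe=st.floats(30.0, 110.0))
def test_lowering_tbi_threshold_only_moves_calls_toward_no_pad(tbi_lower, toe):
    rec = make_record(diabetes=True, brachial=(120.0, 120.0), toe=(toe, toe))
    lowered = Thresholds(tbi_lower=round(tbi_lower - 0.3, 6)) if tbi_lower > 0.31 else None
    base_call = apply_targeted(rec, Thresholds(tbi_lower=tbi_lower)).call
    if lowered is not None:
        low_call = apply_targeted(rec, lowered).call
        assert not (base_call is Call.NO_PAD and low_call is Call.PAD)


def test_screen_cohort_composition_and_exclusion_log():
    cohort = [
        make_record("pad", diabetes=True, brachial=(125.0, 120.0), toe=(50.0, 50.0)),
        make_record("norm", age=70, brachial=(120.0, 118.0), ankle_left=(125.0, 126.0), ankle_right=(125.0, 126.0)),
        make_record("misstoe", diabetes=True, toe=(None, None)),
    ]
    decisions, log = screen_cohort(cohort, Strategy.TARGETED)
    calls = {d.id: d for d in decisions}
    assert calls["pad"].call is Call.PAD
    assert calls["norm"].call is Call.NO_PAD
    assert calls["misstoe"].excluded
    assert log.counts == {"missing toe pressure": 1}

    decisions_aha, log_aha = screen_cohort(cohort, Strategy.AHA)
    assert all(not d.excluded for d in decisions_aha)
    assert not log_aha.counts


def test_screen_cohort_empty_and_different_day_exclusion():
    decisions, log = screen_cohort([], Strategy.AHA)
    assert decisions == [] and not log.counts
    decisions, log = screen_cohort([make_record(duplex_same_day=False)], Strategy.AHA)
    assert decisions[0].excluded and "different day" in decisions[0].reason


def test_screen_cohort_aborts_when_mostly_indeterminate():
    rec = make_record(
        ankle_left=(INCOMPRESSIBLE, INCOMPRESSIBLE),
        ankle_right=(INCOMPRESSIBLE, INCOMPRESSIBLE),
        toe=(None, None),
    )
    with pytest.raises(RuntimeError, match="indeterminate"):
        screen_cohort([rec], Strategy.AHA)


def test_waveform_adjunct_upgrades_negative_screen():
    from limbscreen import Waveform, WaveformPanel

    rec = make_record(age=70, brachial=(100.0, 100.0), ankle_left=(100.0, 100.0), ankle_right=(100.0, 100.0))
    rec.waveforms = WaveformPanel(Waveform.MONOPHASIC, Waveform.BIPHASIC, Waveform.TRIPHASIC, Waveform.TRIPHASIC)
    assert apply_targeted(rec).call is Call.NO_PAD
    adjunct = Thresholds(waveform_adjunct="monophasic_positive")
    assert apply_targeted(rec, adjunct).call is Call.PAD
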