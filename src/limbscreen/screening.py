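"""Eligibility and the two PAD screening strategies.

Both strategies reduce a participant's pressure panel to one binary PAD
call through an index threshold:

* **Targeted** — the test is chosen from medical history: the toe-brachial
  index (TBI) when diabetes or renal disease is present or the participant
  is aged over 75 (populations where calcification degrades the ABI),
  otherwise the ankle-brachial index (ABI).
* **AHA** — ABI for everyone, substituting TBI only when the ABI exceeds
  1.4 (the guideline's incompressibility territory) or the ankle vessels
  are outright incompressible.

A positive screen is ABI < 0.90 or TBI < 0.70 by default.  The boundary
comparisons are strict on both ends ("over 75", "exceeded 1.4").
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .cohort import ParticipantRecord, RiskProfile, Waveform
from .indices import Conventions, IndexKind, IndexResult, IndexState, patient_index


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for both strategies.

    ``abi_lower``/``tbi_lower`` are the positivity cut-offs (dimensionless
    ratios); ``abi_upper`` is the falsely-elevated ceiling that triggers the
    AHA TBI substitution; ``targeted_age_cutoff`` is strict (age > cutoff).
    ``waveform_adjunct`` optionally upgrades a negative screen to positive
    on any monophasic/absent pedal Doppler waveform.
    ``aha_incompressible_to_tbi`` lets an incompressible ABI fall through
    to TBI under the AHA strategy (the guideline's intent for vessels the
    cuff cannot occlude); switch it off to report those screens as
    indeterminate instead.
    """

    abi_lower: float = 0.90
    abi_upper: float = 1.40
    tbi_lower: float = 0.70
    targeted_age_cutoff: int = 75
    waveform_adjunct: str = "off"  # off | monophasic_positive
    aha_incompressible_to_tbi: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.abi_lower < self.abi_upper):
            raise ValueError("require 0 < abi_lower < abi_upper")
        if not (0 < self.tbi_lower < 1):
            raise ValueError("require 0 < tbi_lower < 1")
        if self.waveform_adjunct not in ("off", "monophasic_positive"):
            raise ValueError(f"unknown waveform_adjunct {self.waveform_adjunct!r}")


class Strategy(str, enum.Enum):
    TARGETED = "targeted"
    AHA = "AHA"


class Call(str, enum.Enum):
    PAD = "PAD"
    NO_PAD = "no_PAD"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ScreeningDecision:
    id: str
    strategy: Strategy
    test_used: Optional[IndexKind]
    index_value: Union[float, str, None]  # ratio, "incompressible", or None
    call: Optional[Call]
    excluded: bool = False
    reason: Optional[str] = None


def check_eligibility(risk: RiskProfile) -> bool:
    """AHA vascular-screening eligibility.

    Age over 65, or over 50 with diabetes or current smoking, or exertional
    leg pain at any age.
    """
    return (
        risk.age > 65
        or (risk.age > 50 and (risk.diabetes or risk.current_smoker))
        or risk.exertional_leg_pain
    )


def select_targeted_test(risk: RiskProfile, th: Thresholds = Thresholds()) -> IndexKind:
    """Which index the targeted strategy screens with.

    TBI when diabetes or renal disease is present or age is strictly over
    the cutoff (default 75); ABI otherwise.
    """
    if risk.diabetes or risk.renal_disease or risk.age > th.targeted_age_cutoff:
        return IndexKind.TBI
    return IndexKind.ABI


def _index_value(r: IndexResult) -> Union[float, str, None]:
    if r.state is IndexState.OK:
        return r.value
    if r.state is IndexState.INCOMPRESSIBLE:
        return "incompressible"
    return None


def _waveform_positive(record: ParticipantRecord) -> bool:
    return any(
        w in (Waveform.MONOPHASIC, Waveform.ABSENT) for w in record.waveforms.classes()
    )


def _adjunct(call: Call, record: ParticipantRecord, th: Thresholds) -> Call:
    if (
        th.waveform_adjunct == "monophasic_positive"
        and call is Call.NO_PAD
        and _waveform_positive(record)
    ):
        return Call.PAD
    return call


def _tbi_call(tbi: IndexResult, th: Thresholds) -> Optional[Call]:
    if tbi.state is not IndexState.OK:
        return None
    return Call.PAD if tbi.value < th.tbi_lower else Call.NO_PAD


def apply_targeted(
    record: ParticipantRecord,
    th: Thresholds = Thresholds(),
    conventions: Conventions = Conventions(),
) -> ScreeningDecision:
    """Screen one participant with the targeted strategy.

    When the history selector demands a TBI but no toe pressure exists, the
    participant is excluded (not classifiable by this strategy).  When an
    ABI screen turns out incompressible or above the ceiling, the strategy
    falls through to TBI like the guideline would; only if that rescue TBI
    is also unavailable is the screen indeterminate.
    """
    kind = select_targeted_test(record.risk, th)
    if kind is IndexKind.TBI:
        tbi = patient_index(record.pressures, IndexKind.TBI, conventions)
        if tbi.state is not IndexState.OK:
            return ScreeningDecision(
                record.id, Strategy.TARGETED, IndexKind.TBI, None, None,
                excluded=True, reason="missing toe pressure",
            )
        call = _adjunct(_tbi_call(tbi, th), record, th)
        return ScreeningDecision(
            record.id, Strategy.TARGETED, IndexKind.TBI, tbi.value, call
        )

    abi = patient_index(record.pressures, IndexKind.ABI, conventions)
    if abi.state is IndexState.OK and abi.value <= th.abi_upper:
        call = Call.PAD if abi.value < th.abi_lower else Call.NO_PAD
        call = _adjunct(call, record, th)
        return ScreeningDecision(
            record.id, Strategy.TARGETED, IndexKind.ABI, abi.value, call
        )
    # incompressible, > ceiling, or unavailable: rescue with TBI
    tbi = patient_index(record.pressures, IndexKind.TBI, conventions)
    call = _tbi_call(tbi, th)
    if call is None:
        return ScreeningDecision(
            record.id, Strategy.TARGETED, IndexKind.ABI, _index_value(abi),
            Call.INDETERMINATE, reason="ABI unusable and TBI unavailable",
        )
    return ScreeningDecision(
        record.id, Strategy.TARGETED, IndexKind.TBI, tbi.value, _adjunct(call, record, th)
    )


def apply_aha(
    record: ParticipantRecord,
    th: Thresholds = Thresholds(),
    conventions: Conventions = Conventions(),
) -> ScreeningDecision:
    """Screen one participant with the AHA strategy.

    The ABI is used unless it exceeds ``abi_upper`` (strict) — or is
    incompressible, when the fall-through switch is on — in which case the
    TBI replaces it.  A missing replacement TBI yields an indeterminate
    screen.
    """
    abi = patient_index(record.pressures, IndexKind.ABI, conventions)
    if abi.state is IndexState.OK and abi.value <= th.abi_upper:
        call = Call.PAD if abi.value < th.abi_lower else Call.NO_PAD
        return ScreeningDecision(
            record.id, Strategy.AHA, IndexKind.ABI, abi.value, _adjunct(call, record, th)
        )
    if abi.state is IndexState.INCOMPRESSIBLE and not th.aha_incompressible_to_tbi:
        return ScreeningDecision(
            record.id, Strategy.AHA, IndexKind.ABI, "incompressible",
            Call.INDETERMINATE, reason="incompressible ABI; TBI substitution disabled",
        )
    tbi = patient_index(record.pressures, IndexKind.TBI, conventions)
    call = _tbi_call(tbi, th)
    if call is None:
        return ScreeningDecision(
            record.id, Strategy.AHA, IndexKind.ABI, _index_value(abi),
            Call.INDETERMINATE, reason="ABI unusable and TBI unavailable",
        )
    return ScreeningDecision(
        record.id, Strategy.AHA, IndexKind.TBI, tbi.value, _adjunct(call, record, th)
    )


@dataclass
class ExclusionLog:
    counts: Counter = field(default_factory=Counter)

    def add(self, reason: str) -> None:
        self.counts[reason] += 1


def screen_cohort(
    cohort: Iterable[ParticipantRecord],
    strategy: Strategy,
    th: Thresholds = Thresholds(),
    conventions: Conventions = Conventions(),
    max_indeterminate_frac: float = 0.5,
) -> tuple[list[ScreeningDecision], ExclusionLog]:
    """Apply one strategy to every record.

    Records whose duplex was not performed on the testing day are excluded
    from the analyzable set before screening.  Aborts when more than
    *max_indeterminate_frac* of screened records come back indeterminate,
    which almost always indicates a misconfigured convention or threshold
    block rather than real data.
    """
    apply = apply_targeted if strategy is Strategy.TARGETED else apply_aha
    decisions: list[ScreeningDecision] = []
    log = ExclusionLog()
    for record in cohort:
        if not record.duplex_same_day:
            d = ScreeningDecision(
                record.id, strategy, None, None, None,
                excluded=True, reason="duplex performed on a different day",
            )
        else:
            d = apply(record, th, conventions)
        decisions.append(d)
        if d.excluded:
            log.add(d.reason or "unspecified")
    screened = [d for d in decisions if not d.excluded]
    if screened:
        n_ind = sum(d.call is Call.INDETERMINATE for d in screened)
        if n_ind / len(screened) > max_indeterminate_frac:
            raise RuntimeError(
                f"{n_ind}/{len(screened)} screens indeterminate; "
                "check thresholds/conventions configuration"
            )
    return decisions, log
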