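"""Domain types for lower-limb vascular screening cohorts.

A participant carries a cardiovascular risk profile, a panel of systolic
pressures (brachial, ankle — dorsalis pedis and posterior tibial per limb —
and toe), continuous-wave Doppler waveform classes per pedal artery, and a
set of colour duplex ultrasound findings that serve as the imaging
reference standard for peripheral arterial disease (PAD).

Ankle pressures in calcified (medial arterial calcification, MAC) vessels
may be *incompressible*: the cuff cannot occlude the artery, so no numeric
pressure exists.  Incompressibility is a first-class measurement state
(:data:`INCOMPRESSIBLE`), never a magic number; missing measurements are
``None``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Union


class PressureFlag(enum.Enum):
    """Non-numeric measurement states for a pressure reading."""

    INCOMPRESSIBLE = "incompressible"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Sentinel for an ankle vessel the cuff could not occlude.
INCOMPRESSIBLE = PressureFlag.INCOMPRESSIBLE

#: A pressure cell: a positive value in mmHg, missing, or incompressible.
Pressure = Union[float, None, PressureFlag]

#: Cuff ceiling above which a recorded ankle pressure is reclassified as
#: incompressible (mmHg).  The study population's incompressible fraction is
#: reported, but no ceiling is, so this is configurable.
DEFAULT_CUFF_CEILING = 250.0

#: Plausible age range; records outside it are rejected at load time.
DEFAULT_AGE_RANGE = (18, 110)


def is_incompressible(x: Pressure) -> bool:
    return x is PressureFlag.INCOMPRESSIBLE


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Waveform(str, enum.Enum):
    """Continuous-wave Doppler waveform class of a pedal artery."""

    TRIPHASIC = "triphasic"
    BIPHASIC = "biphasic"
    MONOPHASIC = "monophasic"
    ABSENT = "absent"
    NOT_ASSESSED = "not_assessed"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class RiskProfile:
    """PAD risk factors used by eligibility and test selection."""

    age: int
    sex: Sex
    diabetes: bool
    renal_disease: bool
    current_smoker: bool
    exertional_leg_pain: bool


@dataclass(frozen=True)
class PressurePanel:
    """Bilateral systolic pressures in mmHg.

    Ankle cells may be :data:`INCOMPRESSIBLE`; toe cells may be ``None``
    (missing), which makes the toe-brachial index unavailable on that side.
    """

    brachial_left: Optional[float] = None
    brachial_right: Optional[float] = None
    ankle_dp_left: Pressure = None
    ankle_pt_left: Pressure = None
    ankle_dp_right: Pressure = None
    ankle_pt_right: Pressure = None
    toe_left: Optional[float] = None
    toe_right: Optional[float] = None

    def brachials(self) -> list[float]:
        return [p for p in (self.brachial_left, self.brachial_right) if p is not None]

    def ankles(self, side: Side) -> tuple[Pressure, Pressure]:
        """(dorsalis pedis, posterior tibial) for one limb."""
        if side is Side.LEFT:
            return self.ankle_dp_left, self.ankle_pt_left
        return self.ankle_dp_right, self.ankle_pt_right

    def toe(self, side: Side) -> Optional[float]:
        return self.toe_left if side is Side.LEFT else self.toe_right

    def any_incompressible(self) -> bool:
        return any(
            is_incompressible(p)
            for p in (
                self.ankle_dp_left,
                self.ankle_pt_left,
                self.ankle_dp_right,
                self.ankle_pt_right,
            )
        )


def apply_cuff_ceiling(panel: PressurePanel, ceiling: float = DEFAULT_CUFF_CEILING) -> PressurePanel:
    """Reclassify ankle pressures above *ceiling* as incompressible."""

    def conv(p: Pressure) -> Pressure:
        if isinstance(p, (int, float)) and p > ceiling:
            return INCOMPRESSIBLE
        return p

    return PressurePanel(
        brachial_left=panel.brachial_left,
        brachial_right=panel.brachial_right,
        ankle_dp_left=conv(panel.ankle_dp_left),
        ankle_pt_left=conv(panel.ankle_pt_left),
        ankle_dp_right=conv(panel.ankle_dp_right),
        ankle_pt_right=conv(panel.ankle_pt_right),
        toe_left=panel.toe_left,
        toe_right=panel.toe_right,
    )


@dataclass(frozen=True)
class WaveformPanel:
    """CWD waveform class per pedal artery and limb."""

    dp_left: Waveform = Waveform.NOT_ASSESSED
    pt_left: Waveform = Waveform.NOT_ASSESSED
    dp_right: Waveform = Waveform.NOT_ASSESSED
    pt_right: Waveform = Waveform.NOT_ASSESSED

    def classes(self) -> list[Waveform]:
        return [self.dp_left, self.pt_left, self.dp_right, self.pt_right]


@dataclass(frozen=True)
class DuplexFinding:
    """One duplex-assessed arterial segment.

    ``occluded`` implies 100% stenosis; PAD is defined downstream as any
    segment with stenosis strictly greater than 50%.
    """

    artery: str
    stenosis_percent: float
    occluded: bool = False
    side: Side = Side.LEFT


@dataclass
class ParticipantRecord:
    id: str
    risk: RiskProfile
    pressures: PressurePanel
    waveforms: WaveformPanel = field(default_factory=WaveformPanel)
    duplex: list[DuplexFinding] = field(default_factory=list)
    duplex_same_day: bool = True


@dataclass(frozen=True)
class ValidationFinding:
    """A single invariant violation; ``fatal`` distinguishes rejects from flags."""

    field: str
    message: str
    fatal: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        level = "FATAL" if self.fatal else "WARNING"
        return f"[{level}] {self.field}: {self.message}"


def validate_record(
    record: ParticipantRecord,
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE,
    segment_levels: Optional[dict[str, str]] = None,
) -> list[ValidationFinding]:
    """Check every structural invariant of a participant record.

    Returns one finding per violation (empty list for a conformant record);
    never raises.  Missing toe pressures are a warning — they make the
    toe-brachial index unavailable rather than the record invalid.  When a
    *segment_levels* vocabulary is supplied, duplex artery names are checked
    against it.
    """
    findings: list[ValidationFinding] = []
    r = record.risk
    if not (age_range[0] <= r.age <= age_range[1]):
        findings.append(
            ValidationFinding(
                "risk.age",
                f"age {r.age} outside plausible range {age_range}",
                fatal=True,
            )
        )

    p = record.pressures
    if not p.brachials():
        findings.append(
            ValidationFinding(
                "pressures.brachial",
                "no brachial pressure present; no index can be computed",
                fatal=True,
            )
        )
    for name in (
        "brachial_left",
        "brachial_right",
        "ankle_dp_left",
        "ankle_pt_left",
        "ankle_dp_right",
        "ankle_pt_right",
        "toe_left",
        "toe_right",
    ):
        v = getattr(p, name)
        if isinstance(v, (int, float)) and v <= 0:
            findings.append(
                ValidationFinding(
                    f"pressures.{name}", f"non-positive pressure {v} mmHg", fatal=True
                )
            )
    if p.toe_left is None and p.toe_right is None:
        findings.append(
            ValidationFinding(
                "pressures.toe",
                "toe pressures missing; targeted method may be inapplicable",
                fatal=False,
            )
        )

    for i, f in enumerate(record.duplex):
        loc = f"duplex[{i}]"
        if not (0.0 <= f.stenosis_percent <= 100.0):
            findings.append(
                ValidationFinding(
                    f"{loc}.stenosis_percent",
                    f"stenosis {f.stenosis_percent}% outside [0, 100]",
                    fatal=True,
                )
            )
        if f.occluded and f.stenosis_percent != 100.0:
            findings.append(
                ValidationFinding(
                    f"{loc}.occluded",
                    "occluded segment must carry stenosis_percent = 100",
                    fatal=True,
                )
            )
        if segment_levels is not None and f.artery not in segment_levels:
            findings.append(
                ValidationFinding(
                    f"{loc}.artery",
                    f"unknown arterial segment {f.artery!r}",
                    fatal=True,
                )
            )

    if not record.duplex_same_day:
        findings.append(
            ValidationFinding(
                "duplex_same_day",
                "duplex performed on a different day; record flagged for exclusion",
                fatal=False,
            )
        )
    return findings
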