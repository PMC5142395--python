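"""Ankle-brachial and toe-brachial index computation.

ABI = ankle systolic pressure / brachial systolic pressure.  The dominant
clinical convention — used as the default here — takes the *higher* of the
dorsalis pedis and posterior tibial pressures for the ankle and the
*higher* of the two arm pressures for the denominator; both choices are
configurable because the convention materially changes sensitivity.
TBI = toe systolic pressure / brachial systolic pressure (one toe vessel
per limb, so no ankle-side choice).

An index may be *incompressible* (the selected ankle vessel could not be
occluded by the cuff, typical of medial arterial calcification) or
*unavailable* (a required pressure is missing).  Both are states on the
result, never exceptions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .cohort import INCOMPRESSIBLE, Pressure, PressurePanel, Side, is_incompressible


class IndexKind(str, enum.Enum):
    ABI = "ABI"
    TBI = "TBI"


class IndexState(str, enum.Enum):
    OK = "ok"
    INCOMPRESSIBLE = "incompressible"
    UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class Conventions:
    """Index-computation conventions.

    abi_ankle
        which of DP/PT feeds the ABI numerator (``higher`` | ``lower``).
    brachial
        which arm feeds the denominator (``higher`` | ``lower``).
    limb_aggregation
        how two limb indices collapse to one per-patient value for
        classification: ``worst`` (lower index, the conventional screening
        choice), ``best``, or ``per_limb`` (a patient screens positive if
        any limb does — equivalent to ``worst`` for a threshold call).
    """

    abi_ankle: str = "higher"
    brachial: str = "higher"
    limb_aggregation: str = "worst"

    def __post_init__(self) -> None:
        if self.abi_ankle not in ("higher", "lower"):
            raise ValueError(f"abi_ankle must be higher|lower, got {self.abi_ankle!r}")
        if self.brachial not in ("higher", "lower"):
            raise ValueError(f"brachial must be higher|lower, got {self.brachial!r}")
        if self.limb_aggregation not in ("worst", "best", "per_limb"):
            raise ValueError(
                f"limb_aggregation must be worst|best|per_limb, got {self.limb_aggregation!r}"
            )


@dataclass(frozen=True)
class IndexResult:
    kind: IndexKind
    side: Optional[Side]
    state: IndexState
    value: Optional[float] = None
    numerator_mmHg: Optional[float] = None
    denominator_mmHg: Optional[float] = None

    @property
    def numeric(self) -> bool:
        return self.state is IndexState.OK


def _pick_ankle(dp: Pressure, pt: Pressure, mode: str) -> Pressure:
    """Select the ankle vessel per convention.

    An incompressible vessel exceeds the cuff ceiling, so it compares as
    higher than any numeric reading; a missing vessel never wins.
    """
    present = [p for p in (dp, pt) if p is not None]
    if not present:
        return None
    if len(present) == 1:
        return present[0]
    a, b = present
    if is_incompressible(a) or is_incompressible(b):
        if is_incompressible(a) and is_incompressible(b):
            return INCOMPRESSIBLE
        numeric = b if is_incompressible(a) else a
        return INCOMPRESSIBLE if mode == "higher" else numeric
    return max(a, b) if mode == "higher" else min(a, b)


def _pick_brachial(panel: PressurePanel, mode: str) -> Optional[float]:
    arms = panel.brachials()
    if not arms:
        return None
    return max(arms) if mode == "higher" else min(arms)


def compute_abi(
    pressures: PressurePanel, side: Side, convention: Conventions = Conventions()
) -> IndexResult:
    """Ankle-brachial index for one limb."""
    denom = _pick_brachial(pressures, convention.brachial)
    dp, pt = pressures.ankles(side)
    numer = _pick_ankle(dp, pt, convention.abi_ankle)
    if denom is None or numer is None:
        return IndexResult(IndexKind.ABI, side, IndexState.UNAVAILABLE)
    if is_incompressible(numer):
        return IndexResult(
            IndexKind.ABI, side, IndexState.INCOMPRESSIBLE, denominator_mmHg=denom
        )
    return IndexResult(
        IndexKind.ABI,
        side,
        IndexState.OK,
        value=numer / denom,
        numerator_mmHg=numer,
        denominator_mmHg=denom,
    )


def compute_tbi(
    pressures: PressurePanel, side: Side, convention: Conventions = Conventions()
) -> IndexResult:
    """Toe-brachial index for one limb; unavailable when the toe pressure is missing."""
    denom = _pick_brachial(pressures, convention.brachial)
    toe = pressures.toe(side)
    if denom is None or toe is None:
        return IndexResult(IndexKind.TBI, side, IndexState.UNAVAILABLE)
    return IndexResult(
        IndexKind.TBI,
        side,
        IndexState.OK,
        value=toe / denom,
        numerator_mmHg=toe,
        denominator_mmHg=denom,
    )


def patient_index(
    pressures: PressurePanel, kind: IndexKind, convention: Conventions = Conventions()
) -> IndexResult:
    """Collapse the two limb indices into the per-patient classification value.

    ``worst`` (and ``per_limb``, for a single threshold call) takes the lower
    numeric limb index; ``best`` the higher.  When no limb yields a number,
    the state degrades to incompressible if any limb was, else unavailable.
    """
    compute = compute_abi if kind is IndexKind.ABI else compute_tbi
    limbs = [compute(pressures, s, convention) for s in (Side.LEFT, Side.RIGHT)]
    numeric = [r for r in limbs if r.numeric]
    if numeric:
        if convention.limb_aggregation == "best":
            chosen = max(numeric, key=lambda r: r.value)
        else:  # worst / per_limb
            chosen = min(numeric, key=lambda r: r.value)
        return IndexResult(
            kind,
            None,
            IndexState.OK,
            value=chosen.value,
            numerator_mmHg=chosen.numerator_mmHg,
            denominator_mmHg=chosen.denominator_mmHg,
        )
    if any(r.state is IndexState.INCOMPRESSIBLE for r in limbs):
        return IndexResult(kind, None, IndexState.INCOMPRESSIBLE)
    return IndexResult(kind, None, IndexState.UNAVAILABLE)
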