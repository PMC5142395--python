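"""Duplex-ultrasound reference standard for PAD.

A participant is PAD-positive when any duplex-assessed arterial segment
shows stenosis strictly greater than 50%.  Lesions are classed by level:
*proximal* covers the aorto-iliac through popliteal segments, *distal* the
infrapopliteal (tibial/peroneal/pedal) segments; the boundary lives in an
editable vocabulary file (``data/segments.csv``) so it can be redrawn
without touching code.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Optional

from .cohort import DuplexFinding

#: Stenosis threshold (percent, strict) defining a PAD-positive segment.
PAD_STENOSIS_THRESHOLD = 50.0


class Level(str, enum.Enum):
    NONE = "none"
    DISTAL_ONLY = "distal_only"
    PROXIMAL_ONLY = "proximal_only"
    BOTH = "both"


class OcclusionLevel(str, enum.Enum):
    NONE = "none"
    DISTAL = "distal"
    PROXIMAL = "proximal"
    BOTH = "both"


@dataclass(frozen=True)
class ReferenceLabel:
    pad: bool
    level: Level
    any_occlusion: OcclusionLevel = OcclusionLevel.NONE


def load_segment_map() -> dict[str, str]:
    """The controlled arterial-segment vocabulary: artery name -> proximal|distal."""
    text = resources.files("limbscreen.data").joinpath("segments.csv").read_text()
    out: dict[str, str] = {}
    for row in csv.DictReader(text.splitlines()):
        out[row["artery"]] = row["level"]
    return out


def _territory_level(has_proximal: bool, has_distal: bool) -> Level:
    if has_proximal and has_distal:
        return Level.BOTH
    if has_proximal:
        return Level.PROXIMAL_ONLY
    if has_distal:
        return Level.DISTAL_ONLY
    return Level.NONE


def label_participant(
    findings: Iterable[DuplexFinding], segment_map: Optional[dict[str, str]] = None
) -> ReferenceLabel:
    """Derive the ground-truth PAD label from duplex findings.

    PAD iff any segment stenosis > 50% (strict); the level partitions
    positives by affected territory.  Unknown artery names are fatal.
    Order of findings is irrelevant.
    """
    if segment_map is None:
        segment_map = load_segment_map()
    prox = dist = False
    prox_occ = dist_occ = False
    for f in findings:
        try:
            lvl = segment_map[f.artery]
        except KeyError:
            raise ValueError(f"unknown arterial segment {f.artery!r}") from None
        if f.stenosis_percent > PAD_STENOSIS_THRESHOLD:
            prox |= lvl == "proximal"
            dist |= lvl == "distal"
        if f.occluded:
            prox_occ |= lvl == "proximal"
            dist_occ |= lvl == "distal"
    level = _territory_level(prox, dist)
    occ = {
        (False, False): OcclusionLevel.NONE,
        (True, False): OcclusionLevel.PROXIMAL,
        (False, True): OcclusionLevel.DISTAL,
        (True, True): OcclusionLevel.BOTH,
    }[(prox_occ, dist_occ)]
    return ReferenceLabel(pad=level is not Level.NONE, level=level, any_occlusion=occ)


def round_percent(x: float, mode: str = "half_up", digits: int = 2) -> float:
    """Render a percentage to *digits* decimals.

    ``half_up`` is ordinary commercial rounding; ``truncate`` chops the
    extra digits, which several published summary cells use.
    """
    if mode == "truncate":
        q = 10**digits
        return int(x * q + 1e-9) / q
    if mode == "half_up":
        return float(Decimal(repr(x)).quantize(Decimal(10) ** -digits, rounding=ROUND_HALF_UP))
    raise ValueError(f"unknown rounding mode {mode!r}")


def cohort_prevalence(
    labels: Iterable[ReferenceLabel],
    n_incompressible: int = 0,
    rounding: str = "half_up",
) -> dict[str, tuple[int, float]]:
    """Count/percentage summary of a labelled cohort.

    Returns ``{quantity: (count, percent)}`` with percentages against total
    N to two decimals.  ``n_incompressible`` (participants with at least one
    incompressible ankle pressure) is passed in because labels carry no
    pressure information.
    """
    labels = list(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("cohort_prevalence requires at least one label")

    def pct(k: int) -> float:
        return round_percent(100.0 * k / n, rounding)

    counts = {
        "pad": sum(l.pad for l in labels),
        "distal_only": sum(l.level is Level.DISTAL_ONLY for l in labels),
        "proximal_only": sum(l.level is Level.PROXIMAL_ONLY for l in labels),
        "both": sum(l.level is Level.BOTH for l in labels),
        "distal_occlusion": sum(
            l.any_occlusion in (OcclusionLevel.DISTAL, OcclusionLevel.BOTH) for l in labels
        ),
        "proximal_occlusion": sum(
            l.any_occlusion in (OcclusionLevel.PROXIMAL, OcclusionLevel.BOTH) for l in labels
        ),
        "incompressible": n_incompressible,
    }
    out = {"n_total": (n, 100.0)}
    out.update({k: (v, pct(v)) for k, v in counts.items()})
    return out
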