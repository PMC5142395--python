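"""CSV dialects, run configuration, pipeline orchestration and logging.

Cohort CSV (one row per participant)::

    id,age,sex,diabetes,renal_disease,current_smoker,exertional_leg_pain,
    brachial_left,brachial_right,ankle_dp_left,ankle_pt_left,ankle_dp_right,
    ankle_pt_right,toe_left,toe_right,waveform_dp_left,waveform_pt_left,
    waveform_dp_right,waveform_pt_right,duplex_same_day

The literal token ``INC`` encodes an incompressible ankle pressure; an
empty cell encodes a missing measurement.  Duplex CSV:
``id,side,artery,stenosis_percent,occluded``.  Decisions CSV:
``id,strategy,test_used,index_value,call,excluded,reason``.
All files are RFC-4180, UTF-8, '.' decimal separator.

The run configuration is a single YAML document with four blocks
(``thresholds``, ``conventions``, ``simulation``, ``report``); unknown keys
are rejected and all defaults are materialized on load, so a dumped config
is complete and reload is the identity.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from .cohort import (
    INCOMPRESSIBLE,
    DuplexFinding,
    ParticipantRecord,
    Pressure,
    PressurePanel,
    RiskProfile,
    Sex,
    Side,
    Waveform,
    WaveformPanel,
    apply_cuff_ceiling,
    is_incompressible,
    validate_record,
)
from .dx_stats import (
    AccuracyReport,
    ReportOptions,
    build_contingency,
    full_report,
)
from .indices import Conventions, IndexKind
from .reference import ReferenceLabel, label_participant, load_segment_map
from .screening import (
    Call,
    ExclusionLog,
    ScreeningDecision,
    Strategy,
    Thresholds,
    screen_cohort,
)
from .simulate import Cohort, SimulationConfig, generate_cohort

log = logging.getLogger("limbscreen")

COHORT_COLUMNS = [
    "id", "age", "sex", "diabetes", "renal_disease", "current_smoker",
    "exertional_leg_pain", "brachial_left", "brachial_right",
    "ankle_dp_left", "ankle_pt_left", "ankle_dp_right", "ankle_pt_right",
    "toe_left", "toe_right", "waveform_dp_left", "waveform_pt_left",
    "waveform_dp_right", "waveform_pt_right", "duplex_same_day",
]
DUPLEX_COLUMNS = ["id", "side", "artery", "stenosis_percent", "occluded"]
DECISION_COLUMNS = ["id", "strategy", "test_used", "index_value", "call", "excluded", "reason"]

INCOMPRESSIBLE_TOKEN = "INC"


@dataclass(frozen=True)
class RunConfig:
    """Complete, defaults-materialized configuration of one run."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    conventions: Conventions = field(default_factory=Conventions)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    report: ReportOptions = field(default_factory=ReportOptions)


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config block {path!r} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) under {path!r}: {sorted(unknown)}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        v = data[name]
        sub = f.type if isinstance(f.type, type) else None
        if sub is None:
            # dataclass fields carry string annotations under future-imports
            sub = _NESTED.get((cls.__name__, name))
        if sub is not None and is_dataclass(sub):
            v = _from_plain(sub, v, f"{path}.{name}")
        elif isinstance(v, list):
            v = tuple(v)
        elif isinstance(v, dict):
            v = {k: tuple(x) if isinstance(x, list) else x for k, x in v.items()}
        kwargs[name] = v
    return cls(**kwargs)


from .dx_stats import LrAnnotationRule  # noqa: E402
from .simulate import HemodynamicModel  # noqa: E402

_NESTED = {
    ("RunConfig", "thresholds"): Thresholds,
    ("RunConfig", "conventions"): Conventions,
    ("RunConfig", "simulation"): SimulationConfig,
    ("RunConfig", "report"): ReportOptions,
    ("SimulationConfig", "hemo"): HemodynamicModel,
    ("ReportOptions", "annotation_rule"): LrAnnotationRule,
}


def dump_config(config: RunConfig = RunConfig()) -> str:
    """Serialize a run configuration to YAML with every default spelled out."""
    return yaml.safe_dump(_to_plain(config), sort_keys=False)


def load_config(source: Union[str, Path]) -> RunConfig:
    """Load a YAML run configuration; unknown keys are fatal."""
    text = Path(source).read_text() if isinstance(source, Path) else source
    data = yaml.safe_load(text) or {}
    return _from_plain(RunConfig, data, "run")


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:12]


def log_provenance(config: RunConfig, seed: Optional[int] = None) -> None:
    log.info(
        "limbscreen %s | seed=%s | config=%s",
        __version__,
        config.simulation.seed if seed is None else seed,
        config_hash(config),
    )


# ---------------------------------------------------------------------------
# CSV writers


def _cell(p: Pressure) -> str:
    if p is None:
        return ""
    if is_incompressible(p):
        return INCOMPRESSIBLE_TOKEN
    return repr(float(p))


def write_cohort(records: list[ParticipantRecord], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(COHORT_COLUMNS)
        for r in records:
            p, wf = r.pressures, r.waveforms
            w.writerow([
                r.id, r.risk.age, r.risk.sex.value,
                int(r.risk.diabetes), int(r.risk.renal_disease),
                int(r.risk.current_smoker), int(r.risk.exertional_leg_pain),
                _cell(p.brachial_left), _cell(p.brachial_right),
                _cell(p.ankle_dp_left), _cell(p.ankle_pt_left),
                _cell(p.ankle_dp_right), _cell(p.ankle_pt_right),
                _cell(p.toe_left), _cell(p.toe_right),
                wf.dp_left.value, wf.pt_left.value, wf.dp_right.value, wf.pt_right.value,
                int(r.duplex_same_day),
            ])


def write_duplex(records: list[ParticipantRecord], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DUPLEX_COLUMNS)
        for r in records:
            for f in r.duplex:
                w.writerow([r.id, f.side.value, f.artery, repr(float(f.stenosis_percent)), int(f.occluded)])


def write_decisions(decisions: list[ScreeningDecision], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DECISION_COLUMNS)
        for d in decisions:
            iv = d.index_value
            if isinstance(iv, float):
                iv = f"{iv:.4f}"
            w.writerow([
                d.id, d.strategy.value,
                d.test_used.value if d.test_used else "",
                iv if iv is not None else "",
                d.call.value if d.call else "",
                int(d.excluded), d.reason or "",
            ])


# ---------------------------------------------------------------------------
# CSV readers


class CohortReadError(ValueError):
    """Fatal problem in an input file, with row locations."""


def _parse_pressure(cell: str, where: str) -> Pressure:
    cell = cell.strip()
    if cell == "":
        return None
    if cell == INCOMPRESSIBLE_TOKEN:
        return INCOMPRESSIBLE
    try:
        return float(cell)
    except ValueError:
        raise CohortReadError(f"{where}: malformed pressure {cell!r}") from None


def _parse_bool(cell: str, where: str) -> bool:
    v = cell.strip().lower()
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no"):
        return False
    raise CohortReadError(f"{where}: malformed boolean {cell!r}")


def read_cohort(
    path: Union[str, Path],
    cuff_ceiling: Optional[float] = None,
    validate: bool = True,
) -> list[ParticipantRecord]:
    """Read and validate a cohort CSV.

    Fatal validation findings abort with row numbers; warnings are logged.
    When *cuff_ceiling* is given, numeric ankle pressures above it are
    reclassified as incompressible at load time.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != COHORT_COLUMNS:
            raise CohortReadError(
                f"{path}: header mismatch; expected {COHORT_COLUMNS}, got {reader.fieldnames}"
            )
        records: list[ParticipantRecord] = []
        seen: dict[str, int] = {}
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            rid = row["id"].strip()
            if rid in seen:
                raise CohortReadError(
                    f"{where}: duplicate id {rid!r} (first seen at row {seen[rid]})"
                )
            seen[rid] = lineno
            try:
                sex = Sex(row["sex"].strip().lower())
            except ValueError:
                raise CohortReadError(f"{where}: unknown sex token {row['sex']!r}") from None
            try:
                age = int(row["age"])
            except ValueError:
                raise CohortReadError(f"{where}: malformed age {row['age']!r}") from None
            risk = RiskProfile(
                age=age, sex=sex,
                diabetes=_parse_bool(row["diabetes"], where),
                renal_disease=_parse_bool(row["renal_disease"], where),
                current_smoker=_parse_bool(row["current_smoker"], where),
                exertional_leg_pain=_parse_bool(row["exertional_leg_pain"], where),
            )
            panel = PressurePanel(*[
                _parse_pressure(row[c], where)
                for c in COHORT_COLUMNS[7:15]
            ])
            if cuff_ceiling is not None:
                panel = apply_cuff_ceiling(panel, cuff_ceiling)
            try:
                waveforms = WaveformPanel(*[
                    Waveform(row[c].strip().lower() or "not_assessed")
                    for c in COHORT_COLUMNS[15:19]
                ])
            except ValueError as e:
                raise CohortReadError(f"{where}: {e}") from None
            records.append(
                ParticipantRecord(
                    id=rid, risk=risk, pressures=panel, waveforms=waveforms,
                    duplex_same_day=_parse_bool(row["duplex_same_day"], where),
                )
            )
    if validate:
        fatal: list[str] = []
        for lineno, rec in zip(seen.values(), records):
            for finding in validate_record(rec):
                msg = f"{path}:{lineno}: {finding}"
                if finding.fatal:
                    fatal.append(msg)
                else:
                    log.warning(msg)
        if fatal:
            raise CohortReadError("; ".join(fatal))
    return records


def read_duplex(path: Union[str, Path]) -> dict[str, list[DuplexFinding]]:
    """Read a duplex CSV into findings per participant id (vocabulary-checked)."""
    path = Path(path)
    segments = load_segment_map()
    out: dict[str, list[DuplexFinding]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != DUPLEX_COLUMNS:
            raise CohortReadError(
                f"{path}: header mismatch; expected {DUPLEX_COLUMNS}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            artery = row["artery"].strip()
            if artery not in segments:
                raise CohortReadError(f"{where}: unknown arterial segment {artery!r}")
            try:
                sten = float(row["stenosis_percent"])
            except ValueError:
                raise CohortReadError(
                    f"{where}: malformed stenosis {row['stenosis_percent']!r}"
                ) from None
            f = DuplexFinding(
                artery=artery,
                stenosis_percent=sten,
                occluded=_parse_bool(row["occluded"], where),
                side=Side(row["side"].strip().lower()),
            )
            if not (0.0 <= sten <= 100.0) or (f.occluded and sten != 100.0):
                raise CohortReadError(f"{where}: inconsistent stenosis/occlusion")
            out.setdefault(row["id"].strip(), []).append(f)
    return out


def attach_duplex(
    records: list[ParticipantRecord], duplex: dict[str, list[DuplexFinding]]
) -> None:
    for r in records:
        r.duplex = duplex.get(r.id, [])


def labels_from_duplex(
    records: list[ParticipantRecord]
) -> dict[str, ReferenceLabel]:
    segments = load_segment_map()
    return {r.id: label_participant(r.duplex, segments) for r in records}


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class PipelineResult:
    cohort: Cohort
    decisions: dict[Strategy, list[ScreeningDecision]]
    exclusions: dict[Strategy, ExclusionLog]
    reports: dict[Strategy, AccuracyReport]


def run_pipeline(
    config: RunConfig = RunConfig(),
    cohort_path: Optional[Union[str, Path]] = None,
    duplex_path: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    """Apply both strategies to one cohort and evaluate each against duplex.

    With no input paths the cohort is simulated from ``config.simulation``;
    otherwise both the cohort CSV and the duplex CSV are required.
    """
    log_provenance(config)
    if cohort_path is None:
        cohort = generate_cohort(config.simulation)
    else:
        if duplex_path is None:
            raise ValueError("a duplex CSV is required alongside the cohort CSV")
        records = read_cohort(cohort_path)
        attach_duplex(records, read_duplex(duplex_path))
        cohort = Cohort(records, labels_from_duplex(records))
    result = PipelineResult(cohort, {}, {}, {})
    for strat in Strategy:
        decisions, excl = screen_cohort(
            cohort.records, strat, config.thresholds, config.conventions
        )
        table, dropped = build_contingency(decisions, cohort.labels)
        result.decisions[strat] = decisions
        result.exclusions[strat] = excl
        result.reports[strat] = full_report(
            table, strategy=strat.value, options=config.report, n_excluded=dropped
        )
        log.info(
            "%s: n_analyzed=%d excluded/indeterminate=%d", strat.value, table.n, dropped
        )
    return result
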