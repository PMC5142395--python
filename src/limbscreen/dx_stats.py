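"""Diagnostic-accuracy statistics for a screening strategy.

Everything flows from the 2×2 contingency table of screen call against the
duplex reference standard:

===========  =============  =============
             PAD (duplex)   no PAD
positive     TP             FP
negative     FN             TN
===========  =============  =============

Point estimates: sensitivity TP/(TP+FN), specificity TN/(TN+FP), predictive
values, diagnostic accuracy (TP+TN)/N, and likelihood ratios
LR+ = sens/(1−spec), LR− = (1−sens)/spec.

Confidence intervals: proportions get exact (Clopper–Pearson) binomial
intervals from beta-distribution quantiles; likelihood ratios get the
Simel log-method interval
``exp(ln LR ± z·sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)))`` with (a, b, c, d)
the cells entering the ratio's numerator and denominator proportions.

LR magnitudes are annotated for clinical importance: a test result with
LR+ ≥ 5 or LR− ≤ 0.2 shifts post-test probability enough to be *important*;
LR+ in [2, 5) or LR− in (0.2, 0.5] *may be important*.  The cut-offs are
configurable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy.stats import beta, norm

from .reference import ReferenceLabel, round_percent
from .screening import Call, ScreeningDecision

#: Metrics reported on the percent scale (the rest are ratios).
PERCENT_METRICS = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FN/FP/TN counts for one strategy against the reference standard.

    ``denominator_override`` replaces the analyzed N in the diagnostic
    accuracy denominator only — used to reproduce published accuracy
    figures quoted against the recruited rather than the analyzed cohort.
    """

    tp: int
    fn: int
    fp: int
    tn: int
    denominator_override: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn


class Annotation(str, enum.Enum):
    IMPORTANT = "important"
    MAY_BE_IMPORTANT = "may_be_important"
    NONE = "none"


@dataclass(frozen=True)
class LrAnnotationRule:
    """Importance cut-offs for likelihood-ratio magnitudes."""

    lr_pos_important: float = 5.0
    lr_pos_maybe: float = 2.0
    lr_neg_important: float = 0.2
    lr_neg_maybe: float = 0.5


@dataclass(frozen=True)
class MetricWithCI:
    name: str
    estimate: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_method: Optional[str] = None  # clopper_pearson | lr_log
    annotation: Annotation = Annotation.NONE


@dataclass
class AccuracyReport:
    strategy: str
    n_analyzed: int
    n_excluded: int
    table: ContingencyTable
    metrics: dict[str, MetricWithCI] = field(default_factory=dict)


def build_contingency(
    decisions: Iterable[ScreeningDecision],
    labels: Mapping[str, ReferenceLabel],
) -> tuple[ContingencyTable, int]:
    """Cross-tabulate screen calls against reference labels, joined on id.

    Excluded and indeterminate decisions are dropped from the table; their
    count is returned alongside.  A decision without a matching label is a
    fatal join error.
    """
    tp = fn = fp = tn = dropped = 0
    for d in decisions:
        if d.id not in labels:
            raise KeyError(f"decision id {d.id!r} has no reference label")
        if d.excluded or d.call is Call.INDETERMINATE or d.call is None:
            dropped += 1
            continue
        diseased = labels[d.id].pad
        positive = d.call is Call.PAD
        if diseased:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return ContingencyTable(tp, fn, fp, tn), dropped


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def point_metrics(t: ContingencyTable) -> dict[str, Optional[float]]:
    """All Table-style point estimates.

    Proportion metrics are on the percent scale, likelihood ratios are
    plain ratios.  A metric whose denominator is zero comes back ``None``
    (undefined), never an exception.
    """
    sens = _ratio(t.tp, t.n_diseased)
    spec = _ratio(t.tn, t.n_healthy)
    acc_den = t.denominator_override if t.denominator_override else t.n
    lr_pos = None
    if sens is not None and spec is not None and spec < 1.0:
        lr_pos = sens / (1.0 - spec)
    lr_neg = None
    if sens is not None and spec is not None and spec > 0.0:
        lr_neg = (1.0 - sens) / spec

    def pct(x: Optional[float]) -> Optional[float]:
        return None if x is None else 100.0 * x

    return {
        "sensitivity": pct(sens),
        "specificity": pct(spec),
        "ppv": pct(_ratio(t.tp, t.tp + t.fp)),
        "npv": pct(_ratio(t.tn, t.tn + t.fn)),
        "accuracy": pct(_ratio(t.tp + t.tn, acc_den)),
        "lr_pos": lr_pos,
        "lr_neg": lr_neg,
    }


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes in n trials.

    Lower bound is the α/2 quantile of Beta(k, n−k+1) (0 when k = 0), upper
    the 1−α/2 quantile of Beta(k+1, n−k) (1 when k = n).  Returned on the
    proportion scale.
    """
    if n <= 0 or not (0 <= k <= n):
        raise ValueError(f"invalid Clopper-Pearson input k={k}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


# cells feeding ln-LR variance: (numerator successes, numerator trials,
# denominator successes, denominator trials) as attribute names
_LR_CELLS = {
    "positive": ("tp", "n_diseased", "fp", "n_healthy"),
    "negative": ("fn", "n_diseased", "tn", "n_healthy"),
}


def lr_ci(
    t: ContingencyTable, which: str, level: float = 0.95
) -> Optional[tuple[float, float]]:
    """Simel log-method confidence interval for a likelihood ratio.

    ``var(ln LR) = 1/a − 1/(a+b) + 1/c − 1/(c+d)`` with a/(a+b) the
    numerator proportion and c/(c+d) the denominator proportion of the LR.
    Undefined (``None``) when any of the four cells is zero.
    """
    if which not in _LR_CELLS:
        raise ValueError(f"which must be positive|negative, got {which!r}")
    if min(t.tp, t.fn, t.fp, t.tn) == 0:
        return None
    a_name, an_name, c_name, cn_name = _LR_CELLS[which]
    a, an = getattr(t, a_name), getattr(t, an_name)
    c, cn = getattr(t, c_name), getattr(t, cn_name)
    lr = (a / an) / (c / cn)
    var = 1.0 / a - 1.0 / an + 1.0 / c - 1.0 / cn
    z = float(norm.ppf(1.0 - (1.0 - level) / 2.0))
    half = z * math.sqrt(var)
    return math.exp(math.log(lr) - half), math.exp(math.log(lr) + half)


def annotate_lr(
    lr_pos: Optional[float],
    lr_neg: Optional[float],
    rule: LrAnnotationRule = LrAnnotationRule(),
) -> tuple[Annotation, Annotation]:
    """Clinical-importance annotation for each likelihood ratio."""
    ann_pos = Annotation.NONE
    if lr_pos is not None and math.isfinite(lr_pos):
        if lr_pos >= rule.lr_pos_important:
            ann_pos = Annotation.IMPORTANT
        elif lr_pos >= rule.lr_pos_maybe:
            ann_pos = Annotation.MAY_BE_IMPORTANT
    ann_neg = Annotation.NONE
    if lr_neg is not None and math.isfinite(lr_neg):
        if lr_neg <= rule.lr_neg_important:
            ann_neg = Annotation.IMPORTANT
        elif lr_neg <= rule.lr_neg_maybe:
            ann_neg = Annotation.MAY_BE_IMPORTANT
    return ann_pos, ann_neg


@dataclass(frozen=True)
class ReportOptions:
    """Rendering and CI options for :func:`full_report`.

    ``paper_compat`` truncates (rather than rounds) the diagnostic-accuracy
    row, matching how some published tables chop that cell.
    """

    ci_level: float = 0.95
    rounding: str = "half_up"
    paper_compat: bool = False
    annotation_rule: LrAnnotationRule = LrAnnotationRule()


def full_report(
    t: ContingencyTable,
    strategy: str = "",
    options: ReportOptions = ReportOptions(),
    n_excluded: int = 0,
) -> AccuracyReport:
    """Compose every metric, CI and annotation into one strategy report.

    Estimates keep full precision; use :func:`render_comparison` or
    :func:`report_to_dict` for two-decimal presentation.
    """
    pm = point_metrics(t)
    level = options.ci_level
    metrics: dict[str, MetricWithCI] = {}

    cp_inputs = {
        "sensitivity": (t.tp, t.n_diseased),
        "specificity": (t.tn, t.n_healthy),
        "ppv": (t.tp, t.tp + t.fp),
        "npv": (t.tn, t.tn + t.fn),
    }
    for name, (k, n) in cp_inputs.items():
        if n == 0:
            metrics[name] = MetricWithCI(name, None)
            continue
        low, high = clopper_pearson_ci(k, n, level)
        metrics[name] = MetricWithCI(
            name, pm[name], 100.0 * low, 100.0 * high, "clopper_pearson"
        )

    ann_pos, ann_neg = annotate_lr(pm["lr_pos"], pm["lr_neg"], options.annotation_rule)
    for name, which, ann in (
        ("lr_pos", "positive", ann_pos),
        ("lr_neg", "negative", ann_neg),
    ):
        ci = lr_ci(t, which, level)
        metrics[name] = MetricWithCI(
            name,
            pm[name],
            ci[0] if ci else None,
            ci[1] if ci else None,
            "lr_log" if ci else None,
            annotation=ann,
        )

    metrics["accuracy"] = MetricWithCI("accuracy", pm["accuracy"])
    return AccuracyReport(
        strategy=strategy,
        n_analyzed=t.n,
        n_excluded=n_excluded,
        table=t,
        metrics=metrics,
    )


def _fmt(report: AccuracyReport, name: str, options: ReportOptions) -> dict:
    m = report.metrics[name]
    digits = 2
    mode = options.rounding
    if name == "accuracy" and options.paper_compat:
        mode = "truncate"
    rnd = lambda v: None if v is None else round_percent(v, mode, digits)
    return {
        "estimate": rnd(m.estimate),
        "ci_low": rnd(m.ci_low),
        "ci_high": rnd(m.ci_high),
        "ci_method": m.ci_method,
        "annotation": m.annotation.value,
        "scale": "percent" if name in PERCENT_METRICS else "ratio",
        "rounding": mode,
    }


def report_to_dict(report: AccuracyReport, options: ReportOptions = ReportOptions()) -> dict:
    """JSON-ready report: one object per metric, two-decimal presentation."""
    return {
        "strategy": report.strategy,
        "n_analyzed": report.n_analyzed,
        "n_excluded": report.n_excluded,
        "table": {
            "tp": report.table.tp,
            "fn": report.table.fn,
            "fp": report.table.fp,
            "tn": report.table.tn,
            "denominator_override": report.table.denominator_override,
        },
        "metrics": {name: _fmt(report, name, options) for name in report.metrics},
    }


def render_comparison(
    reports: Iterable[AccuracyReport], options: ReportOptions = ReportOptions()
) -> str:
    """Side-by-side text table of strategy reports (one % and one CI column each)."""
    rows = {
        "sensitivity": "Sensitivity",
        "specificity": "Specificity",
        "ppv": "Positive predictive value",
        "npv": "Negative predictive value",
        "lr_pos": "Positive likelihood ratio",
        "lr_neg": "Negative likelihood ratio",
        "accuracy": "Diagnostic accuracy",
    }
    marks = {Annotation.IMPORTANT: "*", Annotation.MAY_BE_IMPORTANT: "~", Annotation.NONE: ""}
    cols: dict[str, list[str]] = {}
    for rep in reports:
        d = report_to_dict(rep, options)["metrics"]
        est_col, ci_col = [], []
        for name in rows:
            m = d[name]
            est = "" if m["estimate"] is None else f"{m['estimate']:.2f}"
            est += marks[Annotation(m["annotation"])]
            ci = (
                ""
                if m["ci_low"] is None
                else f"{m['ci_low']:.2f} to {m['ci_high']:.2f}"
            )
            est_col.append(est)
            ci_col.append(ci)
        cols[f"{rep.strategy}"] = est_col
        cols[f"{rep.strategy} 95% CI"] = ci_col
    df = pd.DataFrame(cols, index=list(rows.values()))
    legend = "\n* important likelihood ratio   ~ may be important likelihood ratio"
    return df.to_string() + legend
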