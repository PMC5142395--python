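"""Contingency-table statistics: point metrics, exact and log-method CIs,
likelihood-ratio annotations, and internal-consistency properties."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from limbscreen import (
    Annotation,
    Call,
    ContingencyTable,
    ReferenceLabel,
    Level,
    ReportOptions,
    ScreeningDecision,
    Strategy,
    annotate_lr,
    build_contingency,
    clopper_pearson_ci,
    full_report,
    lr_ci,
    point_metrics,
    report_to_dict,
)

TARGETED = ContingencyTable(31, 19, 10, 57)
AHA = ContingencyTable(25, 26, 4, 64)


def test_point_metrics_on_study_tables():
    pm = point_metrics(TARGETED)
    assert pm["sensitivity"] == pytest.approx(62.00, abs=5e-3)
    assert pm["specificity"] == pytest.approx(85.07, abs=5e-3)
    pm2 = point_metrics(AHA)
    assert pm2["ppv"] == pytest.approx(86.21, abs=5e-3)
    assert pm2["npv"] == pytest.approx(71.11, abs=5e-3)
    assert pm2["lr_pos"] == pytest.approx(8.33, abs=5e-3)
    assert pm2["lr_neg"] == pytest.approx(0.54, abs=5e-3)


def test_point_metrics_degenerate_denominators():
    pm = point_metrics(ContingencyTable(0, 0, 0, 10))
    assert pm["sensitivity"] is None
    assert pm["specificity"] == 100.0
    assert pm["lr_pos"] is None  # spec = 1 -> undefined


def test_accuracy_denominator_override():
    t = ContingencyTable(31, 19, 10, 57, denominator_override=119)
    assert point_metrics(t)["accuracy"] == pytest.approx(100 * 88 / 119)
    assert point_metrics(TARGETED)["accuracy"] == pytest.approx(100 * 88 / 117)


def test_clopper_pearson_against_statsmodels():
    from statsmodels.stats.proportion import proportion_confint

    for k, n in [(31, 50), (57, 67), (25, 51), (64, 68), (0, 10), (10, 10), (1, 200)]:
        low, high = clopper_pearson_ci(k, n)
        sm_low, sm_high = proportion_confint(k, n, alpha=0.05, method="beta")
        assert low == pytest.approx(float(sm_low), abs=1e-10, nan_ok=False)
        assert high == pytest.approx(float(sm_high), abs=1e-10)


def test_clopper_pearson_boundaries_closed_form():
    low, high = clopper_pearson_ci(0, 10)
    assert low == 0.0 and high == pytest.approx(1 - 0.025 ** (1 / 10))
    low, high = clopper_pearson_ci(10, 10)
    assert high == 1.0 and low == pytest.approx(0.025 ** (1 / 10))
    with pytest.raises(ValueError):
        clopper_pearson_ci(5, 0)
    with pytest.raises(ValueError):
        clopper_pearson_ci(-1, 10)


def test_clopper_pearson_contains_point_and_narrows_with_n():
    for k, n in [(0, 5), (3, 7), (31, 50), (64, 68), (120, 200)]:
        low, high = clopper_pearson_ci(k, n)
        assert low <= k / n <= high
    widths = []
    for mult in (1, 2, 4, 8):
        low, high = clopper_pearson_ci(3 * mult, 10 * mult)
        widths.append(high - low)
    assert all(w2 <= w1 for w1, w2 in zip(widths, widths[1:]))


def test_lr_ci_matches_hand_computation():
    # hand: ln 4.154 +/- 1.96 * 0.3057... for the (31,19,10,57) table
    assert lr_ci(TARGETED, "positive") == pytest.approx((2.253, 7.655), abs=2e-3)
    assert lr_ci(TARGETED, "negative") == pytest.approx((0.309, 0.645), abs=2e-3)
    # hand: exp(2.1203 +/- 1.96 * 0.5057)
    assert lr_ci(AHA, "positive") == pytest.approx((3.09, 22.45), abs=5e-3)
    assert lr_ci(AHA, "negative") == pytest.approx((0.41, 0.71), abs=5e-3)


def test_lr_ci_undefined_on_zero_cell():
    assert lr_ci(ContingencyTable(5, 0, 3, 7), "negative") is None
    with pytest.raises(ValueError):
        lr_ci(TARGETED, "sideways")


@pytest.mark.parametrize(
    "lr_pos, lr_neg, expected",
    [
        (8.33, 0.54, (Annotation.IMPORTANT, Annotation.NONE)),
        (4.15, 0.45, (Annotation.MAY_BE_IMPORTANT, Annotation.MAY_BE_IMPORTANT)),
        (1.5, 0.8, (Annotation.NONE, Annotation.NONE)),
        (5.0, 0.2, (Annotation.IMPORTANT, Annotation.IMPORTANT)),  # closed boundaries
        (None, None, (Annotation.NONE, Annotation.NONE)),
    ],
)
def test_lr_annotations(lr_pos, lr_neg, expected):
    assert annotate_lr(lr_pos, lr_neg) == expected


def test_build_contingency_counts_and_drops():
    labels = {
        "a": ReferenceLabel(True, Level.DISTAL_ONLY),
        "b": ReferenceLabel(True, Level.DISTAL_ONLY),
        "c": ReferenceLabel(False, Level.NONE),
        "d": ReferenceLabel(False, Level.NONE),
        "e": ReferenceLabel(True, Level.DISTAL_ONLY),
    }

    def dec(i, call, excluded=False):
        return ScreeningDecision(i, Strategy.AHA, None, None, call, excluded)

    decisions = [
        dec("a", Call.PAD),
        dec("b", Call.PAD),
        dec("c", Call.PAD),
        dec("d", Call.NO_PAD),
        dec("e", None, excluded=True),
    ]
    table, dropped = build_contingency(decisions, labels)
    assert (table.tp, table.fn, table.fp, table.tn) == (2, 0, 1, 1)
    assert dropped == 1
    with pytest.raises(KeyError):
        build_contingency([dec("zz", Call.PAD)], labels)


def test_build_contingency_all_excluded_gives_zero_table():
    labels = {"a": ReferenceLabel(False, Level.NONE)}
    d = ScreeningDecision("a", Strategy.AHA, None, None, None, excluded=True)
    table, dropped = build_contingency([d], labels)
    assert table.n == 0 and dropped == 1


def test_full_report_symmetric_table():
    rep = full_report(ContingencyTable(50, 50, 50, 50))
    m = rep.metrics
    for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
        assert m[name].estimate == pytest.approx(50.0)
    assert m["lr_pos"].estimate == pytest.approx(1.0)
    assert m["lr_neg"].estimate == pytest.approx(1.0)


def test_full_report_paper_compat_truncates_accuracy_row_only():
    t = ContingencyTable(31, 19, 10, 57, denominator_override=119)
    d = report_to_dict(full_report(t), ReportOptions(paper_compat=True))
    assert d["metrics"]["accuracy"]["estimate"] == 73.94  # truncated, not 73.95
    assert d["metrics"]["specificity"]["estimate"] == 85.07  # still half-up
    assert d["metrics"]["sensitivity"]["ci_low"] == 47.17


def test_metric_ci_brackets_estimate():
    for t in (TARGETED, AHA, ContingencyTable(5, 3, 2, 8)):
        rep = full_report(t)
        for m in rep.metrics.values():
            if m.estimate is not None and m.ci_low is not None:
                assert m.ci_low <= m.estimate + 1e-9
                assert m.estimate <= m.ci_high + 1e-9


counts = st.integers(min_value=1, max_value=120)


@given(tp=counts, fn=counts, fp=counts, tn=counts)
def test_bayes_consistency_and_lr_identities(tp, fn, fp, tn):
    """PPV/NPV follow from sensitivity, specificity and prevalence exactly,
    and the likelihood ratios factor back into sens/spec."""
    t = ContingencyTable(tp, fn, fp, tn)
    pm = point_metrics(t)
    sens, spec = pm["sensitivity"] / 100, pm["specificity"] / 100
    pi = t.n_diseased / t.n
    ppv = sens * pi / (sens * pi + (1 - spec) * (1 - pi))
    npv = spec * (1 - pi) / (spec * (1 - pi) + (1 - sens) * pi)
    assert pm["ppv"] == pytest.approx(100 * ppv, rel=1e-12)
    assert pm["npv"] == pytest.approx(100 * npv, rel=1e-12)
    assert pm["lr_pos"] * (1 - spec) == pytest.approx(sens, rel=1e-12)
    assert pm["lr_neg"] * spec == pytest.approx(1 - sens, rel=1e-12)
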