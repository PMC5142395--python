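"""Recover 2×2 contingency tables from printed summary statistics.

Published diagnostic-accuracy tables usually print N, disease prevalence,
and two-decimal sensitivity/specificity but not the underlying TP/FN/FP/TN.
Because sensitivity depends only on TP (given the diseased count) and
specificity only on TN, an exhaustive integer search over
``tp ∈ [0, n_diseased]`` × ``tn ∈ [0, n_total − n_diseased]`` recovers every
table consistent with the printed values, making the whole results table
checkable without patient data.

The analyzed-set sizes themselves can be derived: with 119 participants and
51 PAD on duplex, a strategy that excluded two participants for missing toe
pressures reports sensitivity over 50 diseased and specificity over 67
non-diseased only if exactly one exclusion was PAD-positive — which is what
the printed confidence-interval denominators imply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .dx_stats import ContingencyTable, point_metrics


@dataclass(frozen=True)
class SummaryConstraints:
    """Printed summary values constraining the search.

    ``sens``/``spec`` are percentages as printed (two decimals); optional
    ``ppv``/``npv`` (percent) and ``lr_pos``/``lr_neg`` (ratio) are used
    only to rank candidates.  ``tol`` is the half-width of the acceptance
    window on the proportion scale; the default ±0.005 covers any value
    that rounds or truncates to the printed two decimals.
    """

    n_total: int
    n_diseased: int
    sens: float
    spec: float
    ppv: Optional[float] = None
    npv: Optional[float] = None
    lr_pos: Optional[float] = None
    lr_neg: Optional[float] = None
    tol: float = 0.005

    def __post_init__(self) -> None:
        if not (0 <= self.n_diseased <= self.n_total):
            raise ValueError("require 0 <= n_diseased <= n_total")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


def _feasible(count_target: float, n: int, tol: float) -> list[int]:
    """Integers k in [0, n] with |k/n − target| ≤ tol (target on proportion scale)."""
    if n == 0:
        return [0] if count_target <= tol else []
    return [k for k in range(n + 1) if abs(k / n - count_target) <= tol + 1e-12]


def _mismatch(t: ContingencyTable, c: SummaryConstraints) -> float:
    """Sum of squared deviations from the optional cross-validation statistics."""
    pm = point_metrics(t)
    score = 0.0
    for attr, key, scale in (
        ("ppv", "ppv", 100.0),
        ("npv", "npv", 100.0),
        ("lr_pos", "lr_pos", 1.0),
        ("lr_neg", "lr_neg", 1.0),
    ):
        target = getattr(c, attr)
        if target is None:
            continue
        got = pm[key]
        score += 1e6 if got is None else ((got - target) / scale) ** 2
    return score


def recover_counts(c: SummaryConstraints) -> list[ContingencyTable]:
    """Enumerate every contingency table consistent with the printed summary.

    Deterministic; candidates are ranked by agreement with any optional
    cross-validation statistics (ties broken by ascending TP then TN).
    Raises when no table is consistent, with a diagnostic of the nearest
    achievable sensitivity/specificity.
    """
    n_healthy = c.n_total - c.n_diseased
    tps = _feasible(c.sens / 100.0, c.n_diseased, c.tol)
    tns = _feasible(c.spec / 100.0, n_healthy, c.tol)
    if not tps or not tns:
        near_sens = (
            min(range(c.n_diseased + 1), key=lambda k: abs(k / max(c.n_diseased, 1) - c.sens / 100))
            if c.n_diseased else 0
        )
        near_tn = (
            min(range(n_healthy + 1), key=lambda k: abs(k / max(n_healthy, 1) - c.spec / 100))
            if n_healthy else 0
        )
        raise ValueError(
            "no contingency table consistent with the printed summary: "
            f"nearest sensitivity {100 * near_sens / max(c.n_diseased, 1):.2f}% "
            f"(tp={near_sens}/{c.n_diseased}), nearest specificity "
            f"{100 * near_tn / max(n_healthy, 1):.2f}% (tn={near_tn}/{n_healthy}); "
            "widen tol or re-check n_total/n_diseased"
        )
    candidates = [
        ContingencyTable(tp, c.n_diseased - tp, n_healthy - tn, tn)
        for tp in tps
        for tn in tns
    ]
    candidates.sort(key=lambda t: (_mismatch(t, c), t.tp, t.tn))
    return candidates
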