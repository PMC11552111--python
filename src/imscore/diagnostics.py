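"""Diagnostic-test metrics, contingency reconstruction and ROC analysis.

Response scores dichotomised at a threshold (e.g. IMS 1-3 vs 4-5) against a
binary outcome (progression / death) form a 2x2 table, from which
sensitivity, specificity, PPV, NPV (percent, one decimal) and the two-point
trapezoidal AUC = (sensitivity + specificity) / 2 are derived.

Published studies print the metrics but not the tables; given the cohort
size, number of events, number of score-positive patients and any one printed
metric, the integer table is uniquely determined and the remaining metrics
can be recomputed and checked.  :func:`reconstruct_contingency` performs that
inversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import ReconstructionError, ValidationError

__all__ = [
    "ContingencyTable",
    "DiagnosticMetrics",
    "diagnostic_metrics",
    "reconstruct_contingency",
    "contingency_from_labels",
    "ordinal_roc_auc",
    "chi_square_2x2",
]


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.total == 0:
            raise ValidationError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class DiagnosticMetrics:
    """Percent metrics (None when the denominator is zero) and fractional AUC."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    auc: float | None

    def rounded(self) -> dict[str, float | None]:
        """Presentation precision: percents to one decimal, AUC to three."""
        def r(x, nd):
            return None if x is None else float(np.round(x, nd))
        return {"sensitivity": r(self.sensitivity, 1),
                "specificity": r(self.specificity, 1),
                "ppv": r(self.ppv, 1), "npv": r(self.npv, 1),
                "auc": r(self.auc, 3)}


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def diagnostic_metrics(table: ContingencyTable) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV (percent) and binary AUC.

    The AUC of a single dichotomy is the two-point trapezoid
    (sensitivity + specificity) / 2, as a fraction.  Metrics with a zero
    denominator are returned as None ("undefined"), never as 0.
    """
    sens = _ratio(table.tp, table.tp + table.fn)
    spec = _ratio(table.tn, table.tn + table.fp)
    ppv = _ratio(table.tp, table.tp + table.fp)
    npv = _ratio(table.tn, table.tn + table.fn)
    auc = None if sens is None or spec is None else (sens + spec) / 200.0
    return DiagnosticMetrics(sensitivity=sens, specificity=spec,
                             ppv=ppv, npv=npv, auc=auc)


_ANCHORS = ("sensitivity", "ppv")
_ANCHOR_TOL = 0.05  # printed metrics carry one decimal


def reconstruct_contingency(n: int, events: int, positives: int,
                            anchor: tuple[str, float]) -> ContingencyTable:
    """Invert printed marginals + one printed metric into the unique table.

    ``anchor`` is ("sensitivity", value_percent) or ("ppv", value_percent).
    tp is the rounded anchor-implied count; the other cells follow from the
    marginals.  Raises if a cell would be negative or the finished table does
    not reproduce the anchor to within 0.05 percentage points.
    """
    name, value = anchor
    if name not in _ANCHORS:
        raise ReconstructionError(f"anchor must be one of {_ANCHORS}, got {name!r}")
    if not (0 <= events <= n and 0 <= positives <= n):
        raise ReconstructionError("marginals exceed the cohort size")
    base = events if name == "sensitivity" else positives
    if base == 0:
        raise ReconstructionError(f"anchor {name} undefined: zero denominator")
    tp = int(round(value / 100.0 * base))
    fp, fn = positives - tp, events - tp
    tn = n - tp - fp - fn
    if min(tp, fp, fn, tn) < 0:
        raise ReconstructionError(
            f"inconsistent marginals: (tp,fp,fn,tn)=({tp},{fp},{fn},{tn})")
    table = ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)
    recomputed = getattr(diagnostic_metrics(table), name)
    if recomputed is None or abs(recomputed - value) > _ANCHOR_TOL:
        raise ReconstructionError(
            f"reconstructed table gives {name}={recomputed}, printed {value}")
    return table


def contingency_from_labels(positive: Sequence[bool],
                            outcome: Sequence[bool]) -> ContingencyTable:
    """Tabulate predicted-positive flags against true outcomes."""
    p = np.asarray(positive, dtype=bool)
    o = np.asarray(outcome, dtype=bool)
    if p.shape != o.shape:
        raise ValidationError("positive and outcome must have equal length")
    return ContingencyTable(tp=int((p & o).sum()), fp=int((p & ~o).sum()),
                            fn=int((~p & o).sum()), tn=int((~p & ~o).sum()))


def ordinal_roc_auc(scores: Sequence[int], outcomes: Sequence[bool]
                    ) -> tuple[float, tuple[float, float]]:
    """Trapezoidal AUC of an ordinal 1-5 score for a binary outcome.

    Equivalent to the tie-corrected rank-sum statistic.  The 95% CI uses the
    Hanley-McNeil asymptotic variance, clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    o = np.asarray(outcomes, dtype=bool)
    if s.shape != o.shape or s.size < 2:
        raise ValidationError("scores and outcomes must align (n >= 2)")
    n1, n0 = int(o.sum()), int((~o).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("ROC analysis needs both outcome classes")
    auc = float(roc_auc_score(o, s))
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
           + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
    half = 1.96 * float(np.sqrt(max(var, 0.0)))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def chi_square_2x2(table: Sequence[Sequence[float]],
                   continuity_correction: bool = False
                   ) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table; continuity correction off by default.

    The uncorrected statistic is what standard statistical packages report
    for cohort-characteristic comparisons; Yates' correction is available via
    the flag.  Returns (chi2, df=1, p).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValidationError("counts must be nonnegative")
    if arr.sum() <= 0:
        raise ValidationError("empty table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("chi-square undefined: a marginal total is zero")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=continuity_correction)
    return float(chi2), int(df), float(p)
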