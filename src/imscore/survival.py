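"""Endpoint derivation, Kaplan-Meier estimation and the log-rank test.

Progression-free survival (PFS) runs from treatment initiation to disease
progression or death from any cause, whichever comes first; overall survival
(OS) runs from treatment initiation to death.  Patients without the event are
censored at last follow-up.

The product-limit (Kaplan-Meier) estimator and the unweighted k-sample
log-rank test are provided by lifelines; this module wraps them behind the
package's data contracts (strictly positive times, defined-median convention,
validation errors instead of silent NaNs).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import ValidationError

__all__ = ["Endpoints", "KMEstimate", "LogrankResult",
           "compute_endpoints", "km_estimate", "logrank_test"]


@dataclass
class Endpoints:
    pfs_time: float  # days
    pfs_event: bool
    os_time: float
    os_event: bool


def compute_endpoints(treatment_start: date,
                      progression_date: date | None,
                      death_date: date | None,
                      last_followup: date) -> Endpoints:
    """Derive (PFS, OS) intervals and event flags from follow-up dates.

    Death without a recorded progression still counts as a PFS event (the
    endpoint is progression *or* death).
    """
    if last_followup < treatment_start:
        raise ValidationError("last follow-up precedes treatment start")
    for name, d in (("progression", progression_date), ("death", death_date)):
        if d is not None and d < treatment_start:
            raise ValidationError(f"{name} date precedes treatment start")

    event_dates = [d for d in (progression_date, death_date) if d is not None]
    if event_dates:
        pfs = ((min(event_dates) - treatment_start).days, True)
    else:
        pfs = ((last_followup - treatment_start).days, False)
    if death_date is not None:
        os_ = ((death_date - treatment_start).days, True)
    else:
        os_ = ((last_followup - treatment_start).days, False)
    return Endpoints(pfs_time=float(pfs[0]), pfs_event=pfs[1],
                     os_time=float(os_[0]), os_event=os_[1])


@dataclass
class KMEstimate:
    """Product-limit survival estimate.

    ``times`` are the distinct event times, ``survival`` the step-function
    values S(t) at those times.  ``median`` is the smallest t with
    S(t) <= 0.5, or None when the curve never falls that far.
    """

    times: np.ndarray
    survival: np.ndarray
    median: float | None
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_times(times: np.ndarray) -> None:
    if times.size < 1:
        raise ValidationError("survival data must contain at least one subject")
    if (times <= 0).any():
        raise ValidationError("survival times must be strictly positive")


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMEstimate:
    """Kaplan-Meier estimate of the survival function."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    _check_times(t)
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    # drop the t=0 anchor row; keep distinct observed times
    times_out = sf.index.to_numpy(dtype=float)
    surv_out = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times_out > 0
    med = kmf.median_survival_time_
    return KMEstimate(times=times_out[keep], survival=surv_out[keep],
                      median=None if np.isinf(med) else float(med),
                      n=int(t.size), n_events=int(e.sum()))


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float


def logrank_test(times: Sequence[float], events: Sequence[bool],
                 groups: Sequence) -> LogrankResult:
    """Unweighted k-sample log-rank test over pooled event times."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    _check_times(t)
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValidationError("log-rank test needs at least two groups")
    if (counts == 0).any():
        raise ValidationError("every group must be nonempty")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(chi2=float(res.test_statistic),
                         df=int(labels.size - 1),
                         p=float(res.p_value))


def km_table(df: pd.DataFrame, time_col: str, event_col: str,
             group_col: str) -> pd.DataFrame:
    """Per-group KM summary (n, events, median survival) for reporting."""
    rows = []
    for label, sub in df.groupby(group_col, sort=True):
        est = km_estimate(sub[time_col].to_numpy(), sub[event_col].to_numpy())
        rows.append({"group": label, "n": est.n, "events": est.n_events,
                     "median_days": est.median})
    return pd.DataFrame(rows)
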