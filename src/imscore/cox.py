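"""Cox proportional-hazards regression via Newton iteration.

Maximises the partial likelihood with either Breslow (default) or Efron
handling of tied event times, with Wald confidence intervals and p-values per
covariate.  Written in-package because the analysis needs both tie methods
plus an explicit monotone-likelihood (complete-separation) diagnostic behind
one interface; the independent cross-check in the test suite is lifelines'
CoxPHFitter.

Breslow's approximation treats all tied deaths as sharing the full risk set;
Efron's down-weights the tied deaths' own contributions progressively.  On
tie-free data the two are identical.

Monotone likelihood (e.g. all events in one arm of a binary covariate) drives
a coefficient to infinity; the fit is then flagged ``converged=False`` with a
diagnostic message rather than raising, so reports can print "not available"
for that covariate, as survival tables conventionally do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = ["CoxFit", "CovariateEffect", "cox_fit", "cox_score_test"]

_MAX_ITER = 100
_LL_TOL = 1e-9
#: |log-HR| beyond this is treated as monotone likelihood: HRs past e^15 have
#: no clinical meaning and arise only from separation.
_BETA_DIVERGED = 15.0


@dataclass
class CovariateEffect:
    name: str
    log_hr: float
    hr: float
    se: float
    ci_low: float  # 95% Wald, HR scale
    ci_high: float
    p: float


@dataclass
class CoxFit:
    effects: list[CovariateEffect]
    log_likelihood: float
    n: int
    n_events: int
    ties: str
    converged: bool
    message: str = ""
    iterations: int = 0

    def effect(self, name: str) -> CovariateEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def _prepare(times, events, X):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if t.size != e.size or X.shape[0] != t.size:
        raise ValidationError("times, events and covariates must align")
    if (t <= 0).any():
        raise ValidationError("survival times must be positive")
    if e.sum() < 1:
        raise ValidationError("Cox fit needs at least one event")
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise ValidationError(f"covariate {j} is constant")
    order = np.argsort(t, kind="stable")
    return t[order], e[order], X[order]


def _loglik_breslow(beta, t, e, X):
    """Partial log-likelihood, gradient and information (Breslow ties).

    Subjects are sorted by ascending time; risk-set sums are suffix sums of
    exp(x'b), x exp(x'b) and xx' exp(x'b) evaluated at the first index of
    each tied time.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1],
                   axis=0)[::-1]

    # unique event times -> first index in sorted order and death count
    ev_idx = np.flatnonzero(e)
    ut, first_pos, counts = np.unique(t[ev_idx], return_index=True,
                                      return_counts=True)
    # index of first subject at risk (first occurrence of that time overall)
    risk_start = np.searchsorted(t, ut, side="left")

    ll = float(eta[ev_idx].sum())
    grad = X[ev_idx].sum(axis=0)
    info = np.zeros((p, p))
    d = counts.astype(float)
    s0 = S0[risk_start]
    ll -= float((d * np.log(s0)).sum())
    m1 = S1[risk_start] / s0[:, None]
    grad -= (d[:, None] * m1).sum(axis=0)
    m2 = S2[risk_start] / s0[:, None, None]
    info += (d[:, None, None] * (m2 - m1[:, :, None] * m1[:, None, :])).sum(axis=0)
    return ll, grad, info


def _loglik_efron(beta, t, e, X):
    """Partial log-likelihood, gradient and information (Efron ties)."""
    n, p = X.shape
    eta = np.clip(X @ beta, -500, 500)
    w = np.exp(eta)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1],
                   axis=0)[::-1]
    ll, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
    ev_idx = np.flatnonzero(e)
    ut = np.unique(t[ev_idx])
    for tk in ut:
        D = ev_idx[t[ev_idx] == tk]
        d = D.size
        start = int(np.searchsorted(t, tk, side="left"))
        s0, s1, s2 = S0[start], S1[start], S2[start]
        wd = w[D].sum()
        wd1 = (w[D, None] * X[D]).sum(axis=0)
        wd2 = (w[D, None, None] * (X[D][:, :, None] * X[D][:, None, :])).sum(axis=0)
        ll += float(eta[D].sum())
        grad += X[D].sum(axis=0)
        for l in range(d):
            f = l / d
            a0 = s0 - f * wd
            a1 = s1 - f * wd1
            a2 = s2 - f * wd2
            ll -= np.log(a0)
            m1 = a1 / a0
            grad -= m1
            info += a2 / a0 - np.outer(m1, m1)
    return ll, grad, info


def cox_fit(times, events, X, names: list[str] | None = None,
            ties: str = "breslow") -> CoxFit:
    """Fit a Cox PH model; see the module docstring for conventions."""
    if ties not in ("breslow", "efron"):
        raise ValidationError(f"unknown ties method {ties!r}")
    t, e, Xs = _prepare(times, events, X)
    p = Xs.shape[1]
    names = names or [f"x{j}" for j in range(p)]
    loglik = _loglik_breslow if ties == "breslow" else _loglik_efron

    beta = np.zeros(p)
    ll_prev = -np.inf
    converged = False
    message = ""
    info = np.eye(p)
    it = 0
    for it in range(1, _MAX_ITER + 1):
        ll, grad, info = loglik(beta, t, e, Xs)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise ValidationError(
                "singular information matrix (collinear or duplicated covariates)")
        cond = np.linalg.cond(info)
        if cond > 1e12:
            raise ValidationError(
                "singular information matrix (collinear or duplicated covariates)")
        # step-halving if the likelihood would decrease
        scale = 1.0
        for _ in range(20):
            ll_new = loglik(beta + scale * step, t, e, Xs)[0]
            if ll_new >= ll or not np.isfinite(ll_new):
                break
            scale /= 2.0
        beta = beta + scale * step
        if np.abs(beta).max() > _BETA_DIVERGED:
            message = ("monotone partial likelihood: a coefficient diverges "
                       "(complete separation; too few events in one group). "
                       "Hazard ratio not available.")
            break
        if abs(ll - ll_prev) < _LL_TOL:
            converged = True
            break
        ll_prev = ll
    if converged and np.abs(beta).max() > _BETA_DIVERGED:
        converged = False
        message = ("monotone partial likelihood: a coefficient diverges "
                   "(complete separation; too few events in one group). "
                   "Hazard ratio not available.")
    ll, grad, info = loglik(beta, t, e, Xs)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    z = stats.norm.ppf(0.975)
    effects = []
    with np.errstate(over="ignore"):  # separated fits legitimately yield inf CIs
        for j in range(p):
            b, s = float(beta[j]), float(se[j])
            effects.append(CovariateEffect(
                name=names[j], log_hr=b, hr=float(np.exp(b)), se=s,
                ci_low=float(np.exp(b - z * s)), ci_high=float(np.exp(b + z * s)),
                p=float(2 * stats.norm.sf(abs(b) / s)) if s > 0 else float("nan")))
    return CoxFit(effects=effects, log_likelihood=float(ll), n=int(t.size),
                  n_events=int(e.sum()), ties=ties, converged=converged,
                  message=message, iterations=it)


def cox_score_test(times, events, X, ties: str = "breslow") -> tuple[float, float]:
    """Score (Rao) test of beta = 0; on two groups without ties this is the
    log-rank chi-square.  Returns (chi2, p)."""
    t, e, Xs = _prepare(times, events, X)
    loglik = _loglik_breslow if ties == "breslow" else _loglik_efron
    _, grad, info = loglik(np.zeros(Xs.shape[1]), t, e, Xs)
    chi2 = float(grad @ np.linalg.solve(info, grad))
    p = float(stats.chi2.sf(chi2, df=Xs.shape[1]))
    return chi2, p
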