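"""Survival engine: Kaplan-Meier estimation, log-rank test, and
univariate Cox proportional-hazards fitting for a dichotomous marker.

These routines are implemented from first principles (no survival
library behind them) because every (HR, p) pair the screen reports flows
through them.  The Cox fit maximises the partial likelihood for a single
binary covariate by Newton-Raphson with the Efron correction for tied
event times -- median-split markers produce heavy ties, for which Efron
is markedly more accurate than Breslow.

Times are in months.  The screen's convention for 5-year overall
survival is an administrative horizon at 60 months: later events are
recoded as censored at the horizon (see :func:`restrict_horizon`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "KMCurve",
    "CoxResult",
    "kaplan_meier",
    "logrank_test",
    "cox_fit",
    "restrict_horizon",
    "survival_outcome",
    "CoxDichotomous",
]

Z_95 = 1.95996  # two-sided 95% normal quantile


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate as a step function.

    Attributes
    ----------
    event_times : ascending times with at least one observed event
    survival    : S(t) just after each event time
    at_risk     : risk-set size just before each event time
    events      : number of events at each event time
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step-function evaluation (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit for a binary high/low marker.

    ``hr`` is the hazard of the high group relative to low.  ``logrank_p``
    is the two-group log-rank p-value -- the p the screen reports --
    while ``wald_p`` comes from the Wald statistic of the fit itself.
    """

    hr: float
    log_hr: float
    se_log_hr: float
    ci95: tuple[float, float]
    wald_p: float
    logrank_p: float
    n: int
    n_events: int
    converged: bool
    iterations: int


def _as_arrays(time, event, group=None):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if time.ndim != 1 or time.shape != event.shape:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if np.any(time < 0) or not np.all(np.isfinite(time)):
        raise ValueError("times must be finite and non-negative")
    if group is None:
        return time, event
    group = np.asarray(group).astype(bool).ravel()
    if group.shape != time.shape:
        raise ValueError("group must align with time and event")
    return time, event, group


def restrict_horizon(time, event, horizon: float = 60.0):
    """Clip follow-up at an administrative horizon.

    Observations beyond ``horizon`` are recoded as censored at the
    horizon, which turns all-cause follow-up into ``horizon``-restricted
    survival (60 months = 5-year OS).
    """
    time, event = _as_arrays(time, event)
    clipped = np.minimum(time, horizon)
    event = event & (time <= horizon)
    return clipped, event


def kaplan_meier(time, event, label: str | None = None) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod (1 - d_i/n_i).

    Censored observations leave the risk set at their censoring time but
    contribute no factor.  With no observed events the curve is
    identically 1 and ``event_times`` is empty.
    """
    time, event = _as_arrays(time, event)
    if time.size == 0:
        name = f" for group {label!r}" if label else ""
        raise ValueError(f"no samples{name}: cannot estimate a survival curve")

    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    et = time[event]
    uniq, start = np.unique(et, return_index=True)
    d = np.diff(np.append(start, et.size))
    at_risk = time.size - np.searchsorted(time, uniq, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(event_times=uniq, survival=surv, at_risk=at_risk, events=d)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test.

    At each pooled event time the observed events in the high group are
    compared with their hypergeometric expectation given the risk sets;
    the statistic ``(sum O - E)^2 / sum V`` is referred to chi-square
    with 1 df.

    Returns ``(chi_square, p_value)``.
    """
    time, event, group = _as_arrays(time, event, group)
    if group.all() or not group.any():
        raise ValueError("log-rank test requires both marker groups to be non-empty")
    if not event.any():
        raise ValueError("log-rank test requires at least one observed event")

    order = np.argsort(time, kind="stable")
    t_s, e_s, g_s = time[order], event[order], group[order]
    total = t_s.size
    suffix_g = np.cumsum(g_s[::-1].astype(float))[::-1]

    et, eg = t_s[e_s], g_s[e_s]
    uniq, start = np.unique(et, return_index=True)
    d = np.diff(np.append(start, et.size)).astype(float)
    d1 = np.add.reduceat(eg.astype(float), start)
    i0 = np.searchsorted(t_s, uniq, side="left")
    n_at = (total - i0).astype(float)
    n1 = suffix_g[i0]

    o_minus_e = float(np.sum(d1 - d * n1 / n_at))
    informative = n_at > 1
    frac = n1[informative] / n_at[informative]
    var = float(
        np.sum(
            d[informative]
            * frac
            * (1 - frac)
            * (n_at[informative] - d[informative])
            / (n_at[informative] - 1)
        )
    )
    if var <= 0:
        raise ValueError("log-rank variance is zero (no between-group information)")
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def _efron_loglik(beta: float, time, event, x):
    """Partial log-likelihood, score and information with Efron ties.

    ``x`` is the 0/1 group indicator.  Returns (ll, score, info).
    Risk-set sums come from suffix cumulative sums over the
    time-sorted sample, so the cost is O(n log n) regardless of the
    number of distinct event times.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    x = np.asarray(x, dtype=float)

    order = np.argsort(time, kind="stable")
    t_s, e_s, x_s = time[order], event[order], x[order]
    w_s = np.exp(beta * x_s)
    wx_s = w_s * x_s
    c0 = np.cumsum(w_s[::-1])[::-1]  # c0[i] = sum of w over times >= t_s[i]
    c1 = np.cumsum(wx_s[::-1])[::-1]

    et = t_s[e_s]
    uniq, start = np.unique(et, return_index=True)
    counts = np.diff(np.append(start, et.size))
    ew, ewx, ex = w_s[e_s], wx_s[e_s], x_s[e_s]
    d0 = np.add.reduceat(ew, start)
    d1 = np.add.reduceat(ewx, start)
    s = np.add.reduceat(ex, start)
    i0 = np.searchsorted(t_s, uniq, side="left")
    r0, r1 = c0[i0], c1[i0]

    # untied event times (the common case for continuous times): closed form
    single = counts == 1
    mu = r1[single] / r0[single]
    ll = float(beta * np.sum(s) - np.sum(np.log(r0[single])))
    score = float(np.sum(s) - np.sum(mu))
    info = float(np.sum(mu - mu**2))  # x binary: x^2 == x

    for j in np.flatnonzero(~single):
        d = int(counts[j])
        for ell in range(d):
            f = ell / d
            denom = r0[j] - f * d0[j]
            num1 = r1[j] - f * d1[j]
            ll -= float(np.log(denom))
            m = num1 / denom
            score -= m
            info += num1 / denom - m**2
    return ll, score, info


def cox_fit(
    time,
    event,
    group,
    *,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit for a binary marker.

    Newton-Raphson from beta = 0 with step-halving when the partial
    likelihood decreases; Efron correction for tied event times.
    Convergence requires ``|score| < tol``.  Monotone-likelihood data
    (all events on one side, beta diverging) is reported through
    ``converged = False`` rather than an exception, so screens over many
    genes degrade gracefully.
    """
    time, event, group = _as_arrays(time, event, group)
    if group.all() or not group.any():
        raise ValueError("Cox fit requires both marker groups to be non-empty")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("Cox fit requires at least one observed event")

    x = group.astype(float)
    beta = 0.0
    ll, score, info = _efron_loglik(beta, time, event, x)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if abs(score) < tol:
            converged = True
            break
        if info <= 0 or not np.isfinite(info):
            break
        step = score / info
        # step-halving keeps the likelihood from decreasing; the slack
        # keeps float noise in ll (relative ~1e-16) from rejecting the
        # final quadratic-convergence steps near the optimum
        ll_slack = 1e-9 * (abs(ll) + 1.0)
        new_beta = beta + step
        new_ll, new_score, new_info = _efron_loglik(new_beta, time, event, x)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - ll_slack) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _efron_loglik(new_beta, time, event, x)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > 15:
            break
    if abs(score) < tol:
        converged = True
    # monotone likelihood (complete separation): the score can fall under
    # tolerance while beta diverges; a |log HR| beyond 15 (HR > 3e6) is a
    # divergence diagnostic, not an estimate
    if abs(beta) > 15:
        converged = False

    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    hr = float(np.exp(beta))
    with np.errstate(over="ignore"):  # divergent fits get a (0, inf) CI
        ci = (float(np.exp(beta - Z_95 * se)), float(np.exp(beta + Z_95 * se)))
    wald_p = float(2.0 * stats.norm.sf(abs(beta) / se)) if np.isfinite(se) and se > 0 else float("nan")
    _, logrank_p = logrank_test(time, event, group)
    return CoxResult(
        hr=hr,
        log_hr=float(beta),
        se_log_hr=se,
        ci95=ci,
        wald_p=wald_p,
        logrank_p=logrank_p,
        n=int(time.size),
        n_events=n_events,
        converged=converged,
        iterations=iterations,
    )


def survival_outcome(event, time) -> np.ndarray:
    """Pack event indicators and times into a structured outcome array
    (the ``y`` accepted by :class:`CoxDichotomous`)."""
    event = np.asarray(event).astype(bool)
    time = np.asarray(time, dtype=float)
    y = np.empty(event.shape[0], dtype=[("event", "?"), ("time", "<f8")])
    y["event"] = event
    y["time"] = time
    return y


class CoxDichotomous(BaseEstimator):
    """Sklearn-style estimator wrapping the univariate dichotomous Cox fit.

    Parameters
    ----------
    horizon : float or None
        If set, follow-up is clipped at this many months before fitting
        (60 gives 5-year restricted OS).
    tol, max_iter
        Newton-Raphson convergence controls.

    Attributes (after ``fit``)
    --------------------------
    coef_ : log hazard ratio
    hazard_ratio_, se_, conf_int_, wald_p_, logrank_p_ : fit summaries
    result_ : the full :class:`CoxResult`
    """

    def __init__(self, horizon: float | None = 60.0, tol: float = 1e-9, max_iter: int = 50):
        self.horizon = horizon
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("CoxDichotomous handles a single binary covariate")
            X = X[:, 0]
        time = np.asarray(y["time"], dtype=float)
        event = np.asarray(y["event"]).astype(bool)
        if self.horizon is not None:
            time, event = restrict_horizon(time, event, self.horizon)
        res = cox_fit(time, event, X, tol=self.tol, max_iter=self.max_iter)
        self.result_ = res
        self.coef_ = res.log_hr
        self.hazard_ratio_ = res.hr
        self.se_ = res.se_log_hr
        self.conf_int_ = res.ci95
        self.wald_p_ = res.wald_p
        self.logrank_p_ = res.logrank_p
        self.n_iter_ = res.iterations
        self.converged_ = res.converged
        return self

    def predict(self, X):
        """Relative log-hazard of each sample (group indicator times coef_)."""
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[:, 0]
        return X.astype(float) * self.coef_
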