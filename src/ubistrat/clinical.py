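"""Clinical association of the signature: survival, stage/grade, node counts.

Implements the product-limit (Kaplan–Meier) estimator, the k-group log-rank
test, the chi-square test of independence for the group × stage/grade
tables, and a negative-binomial (NB2) GLM with log link for positive-lymph-
node counts, fit by alternating IRLS for the regression coefficients with
univariate Newton maximum likelihood for the dispersion θ (var = μ + μ²/θ).
Wald z statistics use the normal reference, matching the conventional
glm.nb-style summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConvergenceError, DataValidationError


# ---------------------------------------------------------------------------
# survival

@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t): right-continuous step-function lookup."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator.

    Censored observations at an event time are processed after the deaths at
    that time (the standard convention), i.e. they count as at risk there.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise DataValidationError("empty survival input")
    if times.shape != events.shape:
        raise DataValidationError("times and events must have equal length")
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise DataValidationError("survival times must be finite and nonnegative")
    if not np.all(np.isin(events, (0, 1))):
        raise DataValidationError("event flags must be 0 or 1")

    death_times = np.unique(times[events == 1])
    surv = []
    risk = []
    s = 1.0
    for t in death_times:
        n_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        risk.append(n_risk)
    return SurvivalCurve(
        event_times=death_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(risk, int),
    )


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float
    observed: dict
    expected: dict


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence
) -> LogRankResult:
    """k-group log-rank test.

    At each distinct event time the per-group expected death counts are the
    hypergeometric means d·n_g/n and the covariance of the observed counts is
    d(n−d)/(n−1) · (δ_gh·n_g/n − n_g·n_h/n²); the statistic is the quadratic
    form of (O − E) in the generalized inverse of the summed covariance,
    referred to chi-square on k − 1 degrees of freedom.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    if not (len(times) == len(events) == len(groups)):
        raise DataValidationError("times, events, groups must have equal length")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise DataValidationError("log-rank needs at least 2 groups")
    if events.sum() == 0:
        raise DataValidationError("no events observed")

    k = len(levels)
    level_index = {lv: i for i, lv in enumerate(levels)}
    gidx = np.array([level_index[g] for g in groups])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        dead = at_risk & (times == t) & (events == 1)
        d = dead.sum()
        d_g = np.bincount(gidx[dead], minlength=k).astype(float)
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            factor = d * (n - d) / (n - 1.0)
            cov += factor * (np.diag(n_g / n) - np.outer(n_g, n_g) / n**2)

    diff = (observed - expected)[: k - 1]
    vsub = cov[: k - 1, : k - 1]
    chi2 = float(diff @ np.linalg.pinv(vsub) @ diff)
    p = float(stats.chi2.sf(chi2, k - 1))
    return LogRankResult(
        chi2=chi2,
        df=k - 1,
        p=p,
        observed={lv: float(o) for lv, o in zip(levels, observed)},
        expected={lv: float(e) for lv, e in zip(levels, expected)},
    )


# ---------------------------------------------------------------------------
# contingency tables

@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray
    low_expected: bool  # any expected cell below 5


def chi_square_independence(table) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    obs = np.asarray(table, float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DataValidationError("table must be at least 2×2")
    if np.any(obs < 0) or np.any(obs != np.floor(obs)):
        raise DataValidationError("table entries must be nonnegative integers")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DataValidationError("zero marginal total")
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ChiSquareResult(
        chi2=chi2,
        df=df,
        p=float(stats.chi2.sf(chi2, df)),
        expected=expected,
        low_expected=bool((expected < 5).any()),
    )


# ---------------------------------------------------------------------------
# negative-binomial GLM

@dataclass
class NBFit:
    """NB2 GLM fit summary (baseline factor level absorbed in the intercept)."""

    coefficients: dict
    std_errors: dict
    z_values: dict
    p_values: dict
    theta: float
    log_likelihood: float
    converged: bool
    loglik_trace: list = field(default_factory=list)
    theta_capped: bool = False


_THETA_CAP = 1e6


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _irls_beta(
    y: np.ndarray, X: np.ndarray, beta: np.ndarray, theta: float, tol: float = 1e-10
) -> np.ndarray:
    """Fisher-scoring IRLS for β with θ held fixed (log link)."""
    for _ in range(100):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + mu / theta)
        z = eta + (y - mu) / mu
        xtw = X.T * w
        beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


def _theta_score(y: np.ndarray, mu: np.ndarray, theta: float) -> tuple[float, float]:
    """First and second derivatives of the NB log likelihood in θ."""
    s = float(
        np.sum(
            special.digamma(y + theta)
            - special.digamma(theta)
            + np.log(theta / (theta + mu))
            + 1.0
            - (y + theta) / (theta + mu)
        )
    )
    h = float(
        np.sum(
            special.polygamma(1, y + theta)
            - special.polygamma(1, theta)
            + 1.0 / theta
            - 2.0 / (theta + mu)
            + (y + theta) / (theta + mu) ** 2
        )
    )
    return s, h


def fit_negbin_glm(
    counts: Sequence[int],
    group: Optional[Sequence] = None,
    baseline: str = "high",
) -> NBFit:
    """NB2 regression of counts on a categorical factor (or intercept only).

    Alternates IRLS for β given θ with Newton maximum likelihood for θ given
    β until the log likelihood changes by < 1e-8 (at most 100 outer
    iterations).  θ is initialized by the method of moments from Pearson
    residuals of an initial Poisson fit; equidispersed or underdispersed
    data push θ to a 1e6 cap (the Poisson limit) with ``theta_capped`` set.
    Standard errors come from (XᵀWX)⁻¹ at convergence with W = μ/(1 + μ/θ),
    z = β/SE, and two-tailed normal p-values (Wald test).
    """
    y = np.asarray(counts, float)
    if y.size == 0 or np.any(y < 0) or np.any(y != np.floor(y)):
        raise DataValidationError("counts must be nonnegative integers")
    if np.all(y == 0):
        raise DataValidationError("all counts are zero")

    if group is None:
        X = np.ones((len(y), 1))
        names = ["intercept"]
    else:
        group = pd.Series(list(group)).astype(str)
        if len(group) != len(y):
            raise DataValidationError("counts and group must have equal length")
        levels = [lv for lv in pd.unique(group)]
        if baseline not in levels:
            raise DataValidationError(f"baseline level {baseline!r} absent from data")
        others = [lv for lv in levels if lv != baseline]
        X = np.column_stack(
            [np.ones(len(y))] + [(group == lv).to_numpy(float) for lv in others]
        )
        names = ["intercept"] + list(others)
    if len(y) < X.shape[1] + 1:
        raise DataValidationError("too few observations for the design")

    # Poisson start for beta
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    beta = _irls_beta(y, X, beta, theta=_THETA_CAP)
    mu = np.exp(X @ beta)

    # method-of-moments theta from Pearson residuals of the Poisson fit
    num = float(np.sum((y - mu) ** 2 - mu))
    den = float(np.sum(mu**2))
    theta = den / num if num > 0 else _THETA_CAP
    theta = float(np.clip(theta, 1e-3, _THETA_CAP))

    trace = [_nb_loglik(y, mu, theta)]
    converged = False
    for _ in range(100):
        beta = _irls_beta(y, X, beta, theta)
        mu = np.exp(X @ beta)
        # Newton in log-theta, backtracking so the likelihood never decreases
        for _ in range(50):
            s, h = _theta_score(y, mu, theta)
            # derivatives wrt u = log theta: s_u = theta*s ; h_u = theta*s + theta^2*h
            s_u = theta * s
            h_u = theta * s + theta * theta * h
            if h_u >= 0:
                step = np.sign(s_u) * 0.5 if s_u != 0 else 0.0
            else:
                step = -s_u / h_u
            step = float(np.clip(step, -2.0, 2.0))
            if abs(step) < 1e-12:
                break
            ll_cur = _nb_loglik(y, mu, theta)
            theta_new = theta
            for _ in range(30):
                cand = float(np.clip(theta * np.exp(step), 1e-3, _THETA_CAP))
                if _nb_loglik(y, mu, cand) >= ll_cur - 1e-12:
                    theta_new = cand
                    break
                step *= 0.5
            if theta_new == theta:
                break
            theta = theta_new
            if theta in (1e-3, _THETA_CAP):
                break
        ll = _nb_loglik(y, mu, theta)
        trace.append(ll)
        if abs(trace[-1] - trace[-2]) < 1e-8:
            converged = True
            break

    capped = theta >= _THETA_CAP
    if capped:
        warnings.warn(
            "dispersion at the Poisson limit (theta capped at 1e6)", RuntimeWarning
        )

    w = mu / (1.0 + mu / theta)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return NBFit(
        coefficients=dict(zip(names, map(float, beta))),
        std_errors=dict(zip(names, map(float, se))),
        z_values=dict(zip(names, map(float, z))),
        p_values=dict(zip(names, map(float, p))),
        theta=float(theta),
        log_likelihood=float(trace[-1]),
        converged=converged,
        loglik_trace=trace,
        theta_capped=capped,
    )
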