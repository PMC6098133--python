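"""Kaplan-Meier estimation, log-rank comparison and Cox regression.

Times are in months throughout; events are 1 for an observed event and 0
for right censoring, and the tied-time convention is the usual one: events
precede censorings, so a subject censored at an event time is still in the
risk set at that time.

Kaplan-Meier curves and the log-rank test are delegated to lifelines behind
this module's interface.  The Cox proportional-hazards fitter is implemented
here directly — Newton-Raphson on the partial likelihood with either Efron's
or Breslow's correction for tied event times — because both tie conventions
are part of this module's contract.  Backward elimination by Wald p-value
("backward Wald") repeatedly drops the covariate with the largest Wald p
until all remaining p-values fall below the removal threshold, keeping the
initial full model and the elimination trace alongside the final model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "CoxModel",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "cox_fit",
    "backward_wald",
]

SEPARATION_BETA = 15.0  # |beta| beyond this flags monotone likelihood


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate as a right-continuous step function."""

    times: np.ndarray  # event times (strictly increasing)
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_at_risk,
                "n_event": self.n_events,
                "survival": self.survival,
            }
        )


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no subjects")
    if times.size != events.size:
        raise ValueError("times and events differ in length")
    if (times < 0).any():
        raise ValueError("negative survival time")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    mask = table["observed"] > 0
    ev = table[mask]
    return SurvivalCurve(
        times=ev.index.to_numpy(dtype=float),
        n_at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        survival=kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy(),
        n_subjects=int(times.size),
    )


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Evaluate the KM step function right-continuously at time t."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("each group needs at least one subject")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank statistic undefined with zero events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass(frozen=True)
class CoxModel:
    """A fitted proportional-hazards model.

    Per covariate: coefficient beta, its standard error, the hazard ratio
    exp(beta) with normal 95% CI exp(beta +/- 1.96 SE), and the Wald
    statistic (beta/SE)^2 with p from chi-square(1).  ``model_p`` is the
    likelihood-ratio p-value of the whole model against the null.
    """

    covariates: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    ties: str
    n: int
    n_events: int
    n_iter: int
    separation: tuple[str, ...] = ()
    elimination_trace: tuple[tuple[str, float], ...] = ()
    initial_model: "CoxModel | None" = None

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci_lower(self) -> np.ndarray:
        with np.errstate(over="ignore"):  # separation makes SE huge; inf CI is meaningful
            return np.exp(self.beta - 1.96 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.beta + 1.96 * self.se)

    @property
    def wald_stat(self) -> np.ndarray:
        return (self.beta / self.se) ** 2

    @property
    def wald_p(self) -> np.ndarray:
        return sps.chi2.sf(self.wald_stat, df=1)

    @property
    def model_p(self) -> float:
        lr = 2.0 * (self.loglik - self.loglik_null)
        return float(sps.chi2.sf(max(lr, 0.0), df=len(self.covariates)))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "wald_p": self.wald_p,
                "hr": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            },
            index=list(self.covariates),
        )


def _partial_loglik(beta, X, times, events, ties):
    """Log partial likelihood, score vector and Hessian at beta.

    Risk sets are handled by suffix sums over subjects sorted by time; tied
    event times share a risk set and are corrected per Efron or Breslow.
    """
    n, p = X.shape
    order = np.argsort(times, kind="stable")
    Xs = X[order]
    ts = times[order]
    es = events[order]

    eta = Xs @ beta
    eta -= eta.max()  # guard overflow; partial likelihood is shift-invariant up to constant
    theta = np.exp(eta)
    tx = theta[:, None] * Xs
    txx = theta[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])

    # suffix sums: S*[i] = sum over subjects with index >= i (time >= ts[i])
    S0 = np.cumsum(theta[::-1])[::-1]
    S1 = np.cumsum(tx[::-1], axis=0)[::-1]
    S2 = np.cumsum(txx[::-1], axis=0)[::-1]

    loglik = 0.0
    score = np.zeros(p)
    hess = np.zeros((p, p))

    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        d_idx = [k for k in range(i, j) if es[k] == 1]
        d = len(d_idx)
        if d:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            xsum = Xs[d_idx].sum(axis=0)
            loglik += float(eta[d_idx].sum())
            score += xsum
            if ties == "breslow":
                loglik -= d * np.log(s0)
                score -= d * s1 / s0
                hess -= d * (s2 / s0 - np.outer(s1, s1) / s0**2)
            else:  # efron
                sd0 = theta[d_idx].sum()
                sd1 = tx[d_idx].sum(axis=0)
                sd2 = txx[d_idx].sum(axis=0)
                for l in range(d):
                    f = l / d
                    den = s0 - f * sd0
                    num1 = s1 - f * sd1
                    num2 = s2 - f * sd2
                    loglik -= np.log(den)
                    score -= num1 / den
                    hess -= num2 / den - np.outer(num1, num1) / den**2
        i = j
    return loglik, score, hess


def cox_fit(
    covariates: pd.DataFrame,
    times,
    events,
    ties: str = "efron",
    max_iter: int = 100,
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-10,
) -> CoxModel:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    covariates
        Numeric design matrix, one column per covariate, no missing values
        (drop incomplete rows upstream and count them).
    ties : {"efron", "breslow"}
        Correction for tied event times.  Efron is the default for its
        better behaviour with many ties at small n.

    Convergence is declared when the score max-norm falls below 1e-8 or the
    log-likelihood change falls below 1e-10.  Coefficients whose magnitude
    exceeds 15 indicate monotone likelihood (perfect separation) and are
    flagged in ``separation``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    X_df = pd.DataFrame(covariates)
    names = tuple(str(c) for c in X_df.columns)
    X = X_df.to_numpy(dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = X.shape
    if times.size != n or events.size != n:
        raise ValueError("covariates, times and events differ in length")
    if np.isnan(X).any():
        raise ValueError("missing covariate values; drop incomplete rows upstream")
    if events.sum() < 1:
        raise ValueError("no events: partial likelihood is constant")
    for k, name in enumerate(names):
        if np.ptp(X[:, k]) == 0.0:
            raise ValueError(f"covariate {name!r} is constant across subjects")
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("need >= 2 distinct covariate patterns")

    beta = np.zeros(p)
    loglik, score, hess = _partial_loglik(beta, X, times, events, ties)
    loglik_null = loglik
    trace = [loglik]
    for it in range(1, max_iter + 1):
        info = -hess
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                f"singular information matrix at iteration {it}; trace={trace}"
            ) from exc
        # step-halving keeps the likelihood ascending
        new_beta, new = beta + step, None
        for _ in range(30):
            new = _partial_loglik(new_beta, X, times, events, ties)
            if new[0] >= loglik - 1e-12:
                break
            new_beta = (beta + new_beta) / 2
        prev = loglik
        beta, (loglik, score, hess) = new_beta, new
        trace.append(loglik)
        if np.abs(score).max() < tol_score or abs(loglik - prev) < tol_loglik:
            break
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations; loglik trace={trace}"
        )

    separation = tuple(
        names[k] for k in range(p) if abs(beta[k]) > SEPARATION_BETA
    )
    if separation:
        logger.warning(
            "monotone likelihood suspected (|beta| > %.0f) for: %s",
            SEPARATION_BETA,
            ", ".join(separation),
        )
    se = np.sqrt(np.diag(np.linalg.inv(-hess)))
    return CoxModel(
        covariates=names,
        beta=beta,
        se=se,
        loglik=float(loglik),
        loglik_null=float(loglik_null),
        ties=ties,
        n=n,
        n_events=int(events.sum()),
        n_iter=it,
        separation=separation,
    )


def backward_wald(
    covariates: pd.DataFrame,
    times,
    events,
    alpha_remove: float = 0.10,
    ties: str = "efron",
) -> CoxModel:
    """Backward elimination on Wald p-values.

    Starting from the full model, repeatedly refit after removing the
    covariate with the largest Wald p while that p exceeds ``alpha_remove``.
    The returned model carries the elimination trace (covariate, p at
    removal) and the initial full model.
    """
    X = pd.DataFrame(covariates).copy()
    full = cox_fit(X, times, events, ties=ties)
    model = full
    trace: list[tuple[str, float]] = []
    while len(model.covariates) > 1:
        pvals = model.wald_p
        k = int(np.argmax(pvals))
        if pvals[k] <= alpha_remove:
            break
        removed = model.covariates[k]
        trace.append((removed, float(pvals[k])))
        logger.info("backward Wald: removing %s (p = %.4g)", removed, pvals[k])
        X = X.drop(columns=[removed])
        model = cox_fit(X, times, events, ties=ties)
    from dataclasses import replace

    return replace(model, elimination_trace=tuple(trace), initial_model=full)
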