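"""Self-contained survival estimation: Kaplan-Meier and Cox proportional hazards.

This module is the numerical core driven by the gray-zone search.  It
implements:

* the product-limit (Kaplan-Meier) estimator with Greenwood variance,
  95% confidence bands on the log(-log) scale, and the median survival
  time with a band-crossing confidence interval;
* Cox proportional-hazards regression by Newton-Raphson on the partial
  likelihood with Efron (default) or Breslow correction for tied event
  times, Wald intervals, and the score test;
* the nested likelihood-ratio test between Cox models fitted on the same
  subjects, referred to a chi-squared distribution.

Everything is estimated from scratch here; external survival packages are
used only as cross-check oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from grayzone.errors import (
    ComparabilityError,
    DataValidationError,
    DegenerateCovariateError,
)

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass
class SurvivalData:
    """Right-censored times with an optional covariate matrix.

    ``covariates`` is a numeric DataFrame with one column per model term
    (categorical terms already expanded to indicators against a reference
    level); it may have zero columns for a null model.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=range(len(self.time)))
        n = len(self.time)
        if len(self.event) != n or len(self.covariates) != n:
            raise DataValidationError("time, event and covariates must have equal length")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise DataValidationError("survival times must be positive and finite")
        if not np.asarray(self.covariates).size == 0 and np.any(
            ~np.isfinite(np.asarray(self.covariates, dtype=float))
        ):
            raise DataValidationError("covariates must be finite with no missing entries")
        if not self.event.any():
            raise DataValidationError("at least one event is required")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def signature(self) -> bytes:
        """Identifies the subject set (times + events) for nesting checks."""
        order = np.lexsort((self.event, self.time))
        return self.time[order].tobytes() + self.event[order].tobytes()


@dataclass
class KMEstimate:
    """Kaplan-Meier fit: step function values at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float
    median_ci: tuple[float, float]
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Ŝ(t); 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(time: np.ndarray, event: np.ndarray) -> KMEstimate:
    """Product-limit estimate with Greenwood variance and log(-log) CIs.

    The median is the smallest event time with Ŝ <= 0.5 (+inf if the curve
    never reaches 0.5).  Its confidence bounds are the first event times at
    which the lower / upper confidence band drops to <= 0.5, and -inf / +inf
    when the band never crosses.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if len(time) == 0:
        raise DataValidationError("km_fit requires at least one subject")
    if np.any(time <= 0):
        raise DataValidationError("survival times must be positive")

    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]
    n = len(t_sorted)

    uniq = np.unique(t_sorted[e_sorted]) if e_sorted.any() else np.array([])
    surv, var_terms, at_risk_counts, d_counts = [], [], [], []
    s = 1.0
    cum = 0.0
    for t in uniq:
        n_at_risk = int(np.sum(t_sorted >= t))
        d = int(np.sum((t_sorted == t) & e_sorted))
        s *= 1.0 - d / n_at_risk
        if n_at_risk > d:
            cum += d / (n_at_risk * (n_at_risk - d))
        else:
            cum = np.inf  # S hits 0; variance of S is 0 but log-scale blows up
        surv.append(s)
        var_terms.append(cum)
        at_risk_counts.append(n_at_risk)
        d_counts.append(d)

    surv = np.array(surv)
    cumv = np.array(var_terms)
    greenwood = np.where(surv > 0, surv**2 * np.where(np.isfinite(cumv), cumv, 0.0), 0.0)

    # log(-log) scale bands: S^{exp(+/- z * se(log(-log S)))}
    ci_lower = np.full_like(surv, np.nan)
    ci_upper = np.full_like(surv, np.nan)
    interior = (surv > 0) & (surv < 1) & np.isfinite(cumv)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_theta = np.sqrt(cumv[interior]) / np.abs(np.log(surv[interior]))
        ci_lower[interior] = surv[interior] ** np.exp(Z_95 * se_theta)
        ci_upper[interior] = surv[interior] ** np.exp(-Z_95 * se_theta)
    # where S hits 0 the band collapses at 0
    ci_lower[surv == 0] = 0.0
    ci_upper[surv == 0] = 0.0

    median = _first_crossing(uniq, surv)
    med_lo = _first_crossing(uniq, np.where(np.isnan(ci_lower), np.inf, ci_lower))
    med_hi = _first_crossing(uniq, np.where(np.isnan(ci_upper), np.inf, ci_upper))
    median_ci = (med_lo if np.isfinite(med_lo) else -np.inf, med_hi)

    return KMEstimate(
        event_times=uniq,
        survival=surv,
        greenwood_var=greenwood,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        median=median,
        median_ci=median_ci,
        n=n,
        n_events=int(e_sorted.sum()),
    )


def _first_crossing(times: np.ndarray, values: np.ndarray) -> float:
    """Smallest time at which a non-increasing step function is <= 0.5."""
    hits = np.nonzero(values <= 0.5)[0]
    return float(times[hits[0]]) if hits.size else np.inf


@dataclass
class CoxModel:
    """Fitted Cox proportional-hazards model (partial likelihood)."""

    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    hr_ci: np.ndarray  # (p, 2)
    wald_p: np.ndarray
    loglik_null: float
    loglik_fit: float
    score_stat: float
    score_p: float
    n: int
    n_events: int
    converged: bool
    iterations: int
    ties: str
    data_signature: bytes = field(repr=False, default=b"")

    @property
    def n_params(self) -> int:
        return len(self.beta)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "hr": self.hr,
                "hr_lower": self.hr_ci[:, 0],
                "hr_upper": self.hr_ci[:, 1],
                "p": self.wald_p,
            },
            index=list(self.names),
        )


def _partial_loglik_parts(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    ties: str,
    want_derivs: bool,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood with gradient and Hessian.

    Data must be sorted by ascending time.  Risk sets are suffixes of the
    sorted arrays; suffix sums of exp(eta)-weighted moments give the Efron /
    Breslow denominators.  Untied event times are handled fully vectorized;
    only tied groups fall back to a small Python loop.
    """
    n, p = X.shape
    eta = X @ beta if p else np.zeros(n)
    eta_c = eta - eta.max()  # partial likelihood is shift-invariant
    w = np.exp(eta_c)

    s0_suf = np.cumsum(w[::-1])[::-1]  # s0_suf[i] = sum_{j>=i} w_j
    if want_derivs and p:
        wx = w[:, None] * X
        s1_suf = np.cumsum(wx[::-1], axis=0)[::-1]
        wxx = wx[:, :, None] * X[:, None, :]
        s2_suf = np.cumsum(wxx[::-1], axis=0)[::-1]
    else:
        s1_suf = s2_suf = None

    event_times = np.unique(time[event])
    # map each distinct event time to the first sorted position at risk
    start = np.searchsorted(time, event_times, side="left")

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    # counts of events per distinct event time
    ev_time = time[event]
    d_per = np.searchsorted(ev_time, event_times, side="right") - np.searchsorted(
        ev_time, event_times, side="left"
    )

    singles = d_per == 1
    if singles.any():
        # index of the single event row at each untied event time
        ev_idx = np.nonzero(event)[0]
        idx_rows = ev_idx[np.searchsorted(time[ev_idx], event_times[singles], side="left")]
        s0 = s0_suf[start[singles]]
        ll += float(np.sum(eta_c[idx_rows] - np.log(s0)))
        if want_derivs and p:
            z = s1_suf[start[singles]] / s0[:, None]
            grad += X[idx_rows].sum(axis=0) - z.sum(axis=0)
            hess -= np.einsum("kij,k->ij", s2_suf[start[singles]], 1.0 / s0) - np.einsum(
                "ki,kj->ij", z, z
            )

    for t, i0, d in zip(event_times[~singles], start[~singles], d_per[~singles]):
        rows = np.nonzero((time == t) & event)[0]
        s0_r = s0_suf[i0]
        s0_d = w[rows].sum()
        frac = np.arange(d) / d if ties == "efron" else np.zeros(d)
        denom = s0_r - frac * s0_d
        ll += float(eta_c[rows].sum() - np.log(denom).sum())
        if want_derivs and p:
            s1_r = s1_suf[i0]
            s1_d = (w[rows, None] * X[rows]).sum(axis=0)
            s2_r = s2_suf[i0]
            s2_d = np.einsum("k,ki,kj->ij", w[rows], X[rows], X[rows])
            zs = (s1_r[None, :] - frac[:, None] * s1_d[None, :]) / denom[:, None]
            grad += X[rows].sum(axis=0) - zs.sum(axis=0)
            s2s = s2_r[None, :, :] - frac[:, None, None] * s2_d[None, :, :]
            hess -= np.einsum("lij,l->ij", s2s, 1.0 / denom) - np.einsum("li,lj->ij", zs, zs)

    # undo the eta centering: each event contributes +eta_max, each log-denominator
    # absorbs it too, so the net shift cancels exactly; nothing to add back.
    return ll, grad, hess


def cox_fit(data: SurvivalData, ties: str = "efron") -> CoxModel:
    """Newton-Raphson maximization of the tie-corrected log partial likelihood.

    Convergence requires both a relative log-likelihood change below 1e-10
    and a gradient max-norm below 1e-9, within 50 iterations; each Newton
    step is halved at most 10 times until the likelihood does not decrease.
    A monotone likelihood (e.g. a perfectly separating category) yields
    ``converged=False`` with a warning rather than an exception.
    """
    if ties not in ("efron", "breslow"):
        raise DataValidationError(f"unknown tie method {ties!r}")
    X_df = data.covariates
    for col in X_df.columns:
        if X_df[col].nunique() <= 1:
            raise DegenerateCovariateError(f"covariate {col!r} is constant")

    order = np.argsort(data.time, kind="stable")
    time = data.time[order]
    event = data.event[order]
    X = np.asarray(X_df, dtype=float)[order] if X_df.shape[1] else np.empty((data.n, 0))
    p = X.shape[1]

    ll0, _, _ = _partial_loglik_parts(time, event, X, np.zeros(p), ties, want_derivs=False)

    beta = np.zeros(p)
    ll = ll0
    converged = p == 0
    iterations = 0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    if p:
        ll, grad, hess = _partial_loglik_parts(time, event, X, beta, ties, True)
        # score test of all coefficients at beta = 0
        info0 = -hess
        try:
            score_stat = float(grad @ np.linalg.solve(info0, grad))
        except np.linalg.LinAlgError:
            score_stat = np.nan
        for iterations in range(1, 51):
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                warnings.warn("singular information matrix; stopping early", stacklevel=2)
                break
            ll_new = ll
            accepted = False
            # tolerate float rounding in ll, which scales with |ll|
            ll_tol = 1e-10 * (1.0 + abs(ll))
            for _ in range(10):  # step-halving guard
                cand = beta + step
                with np.errstate(over="ignore"):
                    ll_new, g_new, h_new = _partial_loglik_parts(
                        time, event, X, cand, ties, True
                    )
                if np.isfinite(ll_new) and ll_new >= ll - ll_tol:
                    accepted = True
                    break
                step = step / 2.0
            if not accepted:
                break
            delta_ll = ll_new - ll
            beta, ll, grad, hess = cand, ll_new, g_new, h_new
            if abs(delta_ll) / (abs(ll) + 1.0) < 1e-10 and np.max(np.abs(grad)) < 1e-9:
                converged = True
                break
            if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 500:
                break  # monotone likelihood: coefficients diverging
        if not converged:
            warnings.warn(
                "Cox partial likelihood did not converge (possibly monotone "
                "likelihood from a separating covariate); estimates reported as-is",
                stacklevel=2,
            )
    else:
        score_stat = np.nan

    if p:
        info = -hess
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(p, np.inf)
        if converged and (np.max(np.abs(beta)) > 20 or np.any(se > 1e3)):
            # likelihood is monotone in some coefficient (e.g. a perfectly
            # separating category): the Newton criteria were met at a huge
            # finite beta on the likelihood plateau
            converged = False
            warnings.warn(
                "monotone partial likelihood: a coefficient appears infinite; "
                "Wald interval is unbounded",
                stacklevel=2,
            )
        score_p = float(stats.chi2.sf(score_stat, df=p)) if np.isfinite(score_stat) else np.nan
    else:
        se = np.zeros(0)
        score_p = np.nan

    with np.errstate(over="ignore", invalid="ignore"):
        hr = np.exp(beta)
        hr_ci = np.column_stack([np.exp(beta - Z_95 * se), np.exp(beta + Z_95 * se)])
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        wald_p = 2.0 * stats.norm.sf(np.abs(z))

    return CoxModel(
        names=tuple(X_df.columns),
        beta=beta,
        se=se,
        hr=hr,
        hr_ci=hr_ci,
        wald_p=wald_p,
        loglik_null=ll0,
        loglik_fit=ll,
        score_stat=score_stat,
        score_p=score_p,
        n=data.n,
        n_events=data.n_events,
        converged=converged,
        iterations=iterations,
        ties=ties,
        data_signature=data.signature(),
    )


def lrt_nested(full: CoxModel, reduced: CoxModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested Cox models on identical subjects.

    Returns ``(statistic, df, p)`` with statistic = 2 * (ll_full - ll_reduced)
    clipped at 0 and df the difference in estimated coefficients.
    """
    if full.data_signature != reduced.data_signature:
        raise ComparabilityError("nested models must be fitted on the identical subject set")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ComparabilityError("'full' model has fewer parameters than 'reduced'")
    stat = max(0.0, 2.0 * (full.loglik_fit - reduced.loglik_fit))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p
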