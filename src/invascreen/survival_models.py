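"""Survival modelling: Kaplan-Meier, log-rank, and linear-spline Cox regression.

The expression-survival stage models the log hazard as piecewise linear in
a gene's CPM expression with a single knot: covariates min(x, knot) and
max(x - knot, 0), whose hazard ratios are interpreted per 1 CPM increase
below and above the knot.  The knot is chosen by the lowest AIC over a
grid (default 2.0 to 3.0 by 0.1).  The Cox partial likelihood is maximised
by Newton's method with Efron (default) or Breslow tie handling; linearity
is checked with Martingale residuals against a Breslow baseline hazard.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import qth_survival_times

logger = logging.getLogger(__name__)

COVARIATE_VOCABULARY = {
    "idh_status": {"mutant", "wildtype"},
    "mgmt_methylation": {"methylated", "unmethylated"},
    "codeletion_1p19q": {"codeleted", "non-codeleted"},
    "grade": {"2", "3", "4", "LGG", "GBM"},
}


class SurvivalError(ValueError):
    pass


class ConvergenceError(SurvivalError):
    pass


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort TSV with columns time_days, event, expression_cpm (+covariates)."""
    df = pd.read_csv(path, sep="\t")
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("time_days", "event", "expression_cpm"):
        if col not in df.columns:
            raise SurvivalError(f"cohort table missing column {col!r}")
    df = df.copy()
    if df[["time_days", "event", "expression_cpm"]].isna().any().any():
        raise SurvivalError("missing time/event/expression values are not allowed")
    if (df["time_days"] <= 0).any():
        raise SurvivalError("times must be positive")
    if (df["expression_cpm"] < 0).any():
        raise SurvivalError("expression must be non-negative")
    df["event"] = df["event"].astype(int)
    if not df["event"].isin([0, 1]).all():
        raise SurvivalError("event must be 0 (censored) or 1 (death)")
    for col, vocab in COVARIATE_VOCABULARY.items():
        if col in df.columns:
            bad = df[col].dropna().astype(str)
            bad = bad[~bad.isin(vocab)]
            if len(bad):
                raise SurvivalError(f"{col} has levels outside {sorted(vocab)}: "
                                    f"{sorted(bad.unique())[:5]}")
    return df


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank (lifelines-backed)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMEstimate:
    """Product-limit curve plus median and quartile survival times."""

    curve: pd.DataFrame          # columns: time, survival
    median: float
    q75_time: float              # first time S(t) <= 0.75
    q25_time: float              # first time S(t) <= 0.25

    def survival_at(self, t: float) -> float:
        below = self.curve[self.curve["time"] <= t]
        return 1.0 if below.empty else float(below["survival"].iloc[-1])


def km_estimate(times, events) -> KMEstimate:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise SurvivalError("km_estimate requires at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    curve = pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                          "survival": sf.iloc[:, 0].to_numpy(dtype=float)})
    return KMEstimate(
        curve=curve,
        median=float(kmf.median_survival_time_),
        q75_time=float(qth_survival_times(0.75, sf)),
        q25_time=float(qth_survival_times(0.25, sf)),
    )


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    df: int
    p: float


def logrank_test(groups, times, events) -> LogrankResult:
    """Standard observed-minus-expected log-rank test across event times."""
    groups = pd.Series(groups).astype(str)
    counts = groups.value_counts()
    if len(counts) < 2:
        raise SurvivalError("log-rank test needs at least two nonempty groups")
    res = multivariate_logrank_test(np.asarray(times, dtype=float), groups,
                                    np.asarray(events, dtype=int))
    return LogrankResult(chi2=float(res.test_statistic),
                         df=len(counts) - 1,
                         p=float(res.p_value))


def risk_group_split(expression, cutoff: float = 2.5) -> pd.Series:
    """Label subjects high (> cutoff) or low (<= cutoff) risk by expression."""
    expression = pd.Series(expression, dtype=float)
    return pd.Series(np.where(expression > cutoff, "high", "low"),
                     index=expression.index, dtype=object)


# ---------------------------------------------------------------------------
# Cox partial likelihood (Newton, Efron/Breslow ties)
# ---------------------------------------------------------------------------

def spline_basis(x, knot: float) -> np.ndarray:
    """Two-segment linear spline columns (min(x, knot), max(x - knot, 0)).

    The columns reconstruct x exactly: col1 + col2 == x.
    """
    x = np.asarray(x, dtype=float)
    return np.column_stack([np.minimum(x, knot), np.maximum(x - knot, 0.0)])


def _partial_likelihood(beta, time, event, X, ties):
    """Log partial likelihood, gradient and observed information.

    Arrays must be sorted by time ascending.  Efron's correction subtracts
    l/d of the tied-death sums from the risk-set sums for l = 0..d-1;
    Breslow uses the full risk-set sums d times (frac = 0).
    """
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = w[:, None, None] * (X[:, :, None] * X[:, None, :])
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev = np.flatnonzero(event == 1)
    ev_t = time[ev]
    uniq, starts = np.unique(ev_t, return_index=True)
    d = np.diff(np.append(starts, len(ev)))
    risk_idx = np.searchsorted(time, uniq, side="left")

    s0d = np.add.reduceat(w[ev], starts)
    s1d = np.add.reduceat(wx[ev], starts, axis=0)
    s2d = np.add.reduceat(wxx[ev], starts, axis=0)

    rep = np.repeat(np.arange(len(uniq)), d)
    l = np.arange(len(ev)) - np.repeat(starts, d)
    frac = (l / d[rep]) if ties == "efron" else np.zeros(len(ev))

    S0 = s0[risk_idx][rep] - frac * s0d[rep]
    S1 = s1[risk_idx][rep] - frac[:, None] * s1d[rep]
    S2 = s2[risk_idx][rep] - frac[:, None, None] * s2d[rep]

    loglik = eta[ev].sum() - np.log(S0).sum()
    mean = S1 / S0[:, None]
    grad = X[ev].sum(axis=0) - mean.sum(axis=0)
    info = (S2 / S0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", mean, mean)
    return loglik, grad, info


@dataclass(frozen=True)
class CoxFit:
    """Maximum partial-likelihood Cox fit with Wald inference."""

    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    n: int
    n_events: int
    ties: str
    converged: bool
    n_iter: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    def hr_ci(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        return np.exp(np.column_stack([self.beta - z * self.se, self.beta + z * self.se]))

    def wald_p(self) -> np.ndarray:
        from scipy.stats import norm
        return 2 * norm.sf(np.abs(self.beta / self.se))


def _prepare(time, event, X):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.shape[0]:
        X = X.T
    if event.sum() < 1:
        raise SurvivalError("Cox fit requires at least one event")
    if np.any(X.std(axis=0) == 0):
        raise SurvivalError("constant covariate column")
    order = np.argsort(time, kind="stable")
    return time[order], event[order], X[order]


def cox_fit(time, event, X, ties: str = "efron",
            tol: float = 1e-8, max_iter: int = 100) -> CoxFit:
    """Newton maximisation of the Cox partial likelihood.

    Iterates to gradient norm < ``tol`` (default 1e-8) or ``max_iter``,
    with step halving if a step decreases the likelihood.  On large cohorts
    the absolute gradient norm is limited by floating-point accumulation,
    so a vanishing Newton decrement grad' H^-1 grad (relative to the
    log-likelihood magnitude) also counts as convergence.  Raises
    :class:`ConvergenceError` on non-convergence, singular information, or
    monotone likelihood (coefficients diverging, e.g. perfect separation).
    """
    if ties not in ("efron", "breslow"):
        raise SurvivalError(f"unknown tie handling {ties!r}")
    time, event, X = _prepare(time, event, X)
    n, p = X.shape
    beta = np.zeros(p)
    loglik, grad, info = _partial_likelihood(beta, time, event, X, ties)
    n_iter = 0
    converged = False
    ll_scale = max(1.0, abs(loglik))
    for n_iter in range(1, max_iter + 1):
        if np.linalg.norm(grad) < tol:
            converged = True
            n_iter -= 1
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix at iteration {n_iter}") from exc
        # likelihood gain below machine precision relative to |log L|:
        # no representable improvement remains
        if grad @ step < 1e-16 * ll_scale:
            converged = True
            n_iter -= 1
            break
        # step halving keeps the likelihood ascent monotone
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            new_ll, new_grad, new_info = _partial_likelihood(candidate, time, event, X, ties)
            if np.isfinite(new_ll) and new_ll >= loglik - 1e-10 * ll_scale:
                break
            scale /= 2.0
        else:
            raise ConvergenceError("step halving failed to improve the likelihood")
        beta, loglik, grad, info = candidate, new_ll, new_grad, new_info
        if np.abs(beta).max() > 500:
            raise ConvergenceError(
                "coefficients diverging (monotone likelihood / perfect separation?)"
            )
    if not converged and np.linalg.norm(grad) < tol:
        converged = True
    if not converged:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (|grad| = {np.linalg.norm(grad):.3g})"
        )
    # a partial likelihood at its supremum (log ~ 0) or an extreme coefficient
    # means the gradient vanished because the likelihood is monotone in beta
    if loglik > -1e-3 or np.abs(beta).max() > 50:
        raise ConvergenceError(
            "monotone likelihood (perfect separation?): "
            f"loglik = {loglik:.3g}, max|beta| = {np.abs(beta).max():.3g}"
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular information matrix at the optimum") from exc
    return CoxFit(
        beta=beta, se=np.sqrt(np.diag(cov)), cov=cov,
        loglik=float(loglik), aic=float(-2 * loglik + 2 * p),
        n=n, n_events=int(event.sum()), ties=ties,
        converged=True, n_iter=n_iter,
    )


def cox_score_test(time, event, X, ties: str = "breslow") -> tuple[float, float]:
    """Score test of beta = 0: U' I^{-1} U with its chi-square p-value.

    With a single group-indicator covariate and Breslow ties this is the
    log-rank statistic.
    """
    from scipy.stats import chi2 as chi2_dist
    time, event, X = _prepare(time, event, X)
    _, grad, info = _partial_likelihood(np.zeros(X.shape[1]), time, event, X, ties)
    stat = float(grad @ np.linalg.solve(info, grad))
    return stat, float(chi2_dist.sf(stat, X.shape[1]))


@dataclass(frozen=True)
class SplineCoxFit:
    """Two-segment spline Cox fit: per-CPM hazard ratios below/above the knot."""

    knot: float
    beta_below: float
    beta_above: float
    se_below: float
    se_above: float
    hr_below: float
    hr_below_ci: tuple[float, float]
    hr_above: float
    hr_above_ci: tuple[float, float]
    p_below: float
    p_above: float
    loglik: float
    aic: float
    n: int
    n_events: int
    fit: CoxFit

    def to_dict(self) -> dict:
        return {
            "knot": self.knot,
            "beta_below": self.beta_below, "beta_above": self.beta_above,
            "se_below": self.se_below, "se_above": self.se_above,
            "hr_below": self.hr_below, "hr_below_ci": list(self.hr_below_ci),
            "hr_above": self.hr_above, "hr_above_ci": list(self.hr_above_ci),
            "p_below": self.p_below, "p_above": self.p_above,
            "loglik": self.loglik, "aic": self.aic,
            "n": self.n, "n_events": self.n_events,
        }


def fit_spline_cox(cohort: pd.DataFrame, knot: float = 2.5,
                   ties: str = "efron") -> SplineCoxFit:
    """Fit the piecewise-linear expression Cox model at a fixed knot."""
    x = cohort["expression_cpm"].to_numpy(dtype=float)
    if not (x.min() < knot < x.max()):
        raise SurvivalError(f"knot {knot} outside the observed expression range "
                            f"[{x.min():.3g}, {x.max():.3g}]")
    X = spline_basis(x, knot)
    fit = cox_fit(cohort["time_days"], cohort["event"], X, ties=ties)
    ci = fit.hr_ci()
    p = fit.wald_p()
    return SplineCoxFit(
        knot=knot,
        beta_below=float(fit.beta[0]), beta_above=float(fit.beta[1]),
        se_below=float(fit.se[0]), se_above=float(fit.se[1]),
        hr_below=float(fit.hr[0]), hr_below_ci=(float(ci[0, 0]), float(ci[0, 1])),
        hr_above=float(fit.hr[1]), hr_above_ci=(float(ci[1, 0]), float(ci[1, 1])),
        p_below=float(p[0]), p_above=float(p[1]),
        loglik=fit.loglik, aic=fit.aic, n=fit.n, n_events=fit.n_events,
        fit=fit,
    )


@dataclass(frozen=True)
class KnotSearchResult:
    best_knot: float
    aic_profile: dict[float, float]   # knot -> AIC, converged knots only
    best_fit: SplineCoxFit


def knot_search(cohort: pd.DataFrame, grid_lo: float = 2.0, grid_hi: float = 3.0,
                step: float = 0.1, ties: str = "efron") -> KnotSearchResult:
    """Choose the spline knot by the lowest AIC over a grid; ties to the smaller knot."""
    if step <= 0 or grid_hi < grid_lo:
        raise SurvivalError("invalid knot grid")
    n_steps = int(round((grid_hi - grid_lo) / step))
    knots = np.round(grid_lo + step * np.arange(n_steps + 1), 10)
    profile: dict[float, float] = {}
    fits: dict[float, SplineCoxFit] = {}
    for knot in knots:
        try:
            fit = fit_spline_cox(cohort, knot=float(knot), ties=ties)
        except (SurvivalError, ConvergenceError) as exc:
            warnings.warn(f"knot {knot}: fit failed ({exc}); skipped", stacklevel=2)
            continue
        profile[float(knot)] = fit.aic
        fits[float(knot)] = fit
    if not profile:
        raise SurvivalError("no knot on the grid produced a converged fit")
    # ascending grid order means the first minimum wins ties toward smaller knots
    best = min(profile, key=lambda k: (profile[k], k))
    return KnotSearchResult(best_knot=best, aic_profile=profile, best_fit=fits[best])


def martingale_residuals(fit: CoxFit, time, event, X) -> np.ndarray:
    """Per-subject Martingale residual: event minus fitted cumulative hazard.

    The baseline cumulative hazard is the Breslow estimator at the fitted
    coefficients.  Residuals sum to zero identically by the estimator's
    construction.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.shape[0]:
        X = X.T
    order = np.argsort(time, kind="stable")
    ts, es, Xs = time[order], event[order], X[order]
    w = np.exp(Xs @ fit.beta)
    s0 = np.cumsum(w[::-1])[::-1]
    ev = np.flatnonzero(es == 1)
    uniq, starts = np.unique(ts[ev], return_index=True)
    d = np.diff(np.append(starts, len(ev)))
    risk_idx = np.searchsorted(ts, uniq, side="left")
    increments = d / s0[risk_idx]
    cum_h0 = np.cumsum(increments)
    # baseline cumulative hazard at each subject's exit time
    pos = np.searchsorted(uniq, time, side="right")
    h0_at_exit = np.where(pos > 0, cum_h0[np.maximum(pos - 1, 0)], 0.0)
    return event - h0_at_exit * np.exp(X @ fit.beta)
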