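"""Cox proportional-hazards fitting, log-rank testing and analysis of deviance.

This module is the statistical engine shared by the CpG screening filter and
the cohort-level prognosis comparisons.  The Cox model maximises the partial
likelihood with Efron's approximation for tied event times using damped Newton
iterations; the log-rank test uses the usual hypergeometric-variance form over
distinct event times; nested Cox models are compared by a likelihood-ratio
("analysis of deviance") chi-square.

All procedures here are deterministic: there is no internal randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxFitResult",
    "LogRankResult",
    "KaplanMeierCurve",
    "cox_fit",
    "cox_loglik",
    "logrank",
    "deviance_compare",
    "kaplan_meier",
]


class CoxError(ValueError):
    """Raised for degenerate Cox inputs (no events, no variation, singular fit)."""


@dataclass
class CoxFitResult:
    """Result of a Cox proportional-hazards fit.

    ``hazard_ratios`` are ``exp(coefficients)``; ``ci95`` are Wald intervals
    ``exp(coef ± 1.96·se)``.  ``log_likelihood_null`` is the partial
    log-likelihood at β = 0, kept so that a likelihood-ratio test against the
    empty model needs no refit.
    """

    covariates: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    log_likelihood_null: float
    n: int
    n_events: int
    n_iter: int = 0
    score_at_zero: np.ndarray | None = field(default=None, repr=False)
    information_at_zero: np.ndarray | None = field(default=None, repr=False)

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def ci95(self) -> np.ndarray:
        """(k, 2) array of 95% hazard-ratio confidence limits."""
        delta = 1.959963984540054 * self.standard_errors
        with np.errstate(over="ignore"):  # near-separation: infinite bound is honest
            return np.exp(
                np.column_stack([self.coefficients - delta, self.coefficients + delta])
            )

    @property
    def p_wald(self) -> np.ndarray:
        z = self.coefficients / self.standard_errors
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "hr": self.hazard_ratios,
                "hr_ci_low": ci[:, 0],
                "hr_ci_high": ci[:, 1],
                "p": self.p_wald,
            },
            index=self.covariates,
        )


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p: float
    groups: list
    observed: np.ndarray
    expected: np.ndarray


def _prepare(covariates, survival: pd.DataFrame):
    """Align covariates with a survival table and drop incomplete rows."""
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    if isinstance(covariates, pd.DataFrame):
        X = covariates
    else:
        X = pd.DataFrame(np.asarray(covariates, dtype=float))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
        X.index = survival.index
    X = X.loc[survival.index]
    keep = X.notna().all(axis=1) & survival["time_months"].notna()
    X = X.loc[keep]
    t = survival.loc[keep, "time_months"].to_numpy(dtype=float)
    e = survival.loc[keep, "event"].to_numpy(dtype=int)
    return X, t, e


def _efron_quantities(beta, X, t, e):
    """Partial log-likelihood, gradient and Hessian under Efron tie handling.

    Rows are pre-sorted by ascending time.  The tie-free path is fully
    vectorised; ties fall back to a per-event-time loop.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # rescale for overflow safety; cancels in ratios
    theta = np.exp(eta)

    # reverse cumulative sums: S0[i] = sum_{j >= i} theta_j etc.
    S0 = np.cumsum(theta[::-1])[::-1]
    Xw = X * theta[:, None]
    S1 = np.cumsum(Xw[::-1], axis=0)[::-1]
    XX = X[:, :, None] * X[:, None, :] * theta[:, None, None]
    S2 = np.cumsum(XX[::-1], axis=0)[::-1]

    ev = np.flatnonzero(e == 1)
    t_ev = t[ev]
    tied = len(np.unique(t_ev)) < len(t_ev)

    if not tied:
        s0 = S0[ev]
        s1 = S1[ev]
        s2 = S2[ev]
        ll = float(np.sum(eta[ev] - np.log(s0)))
        mean1 = s1 / s0[:, None]
        grad = X[ev].sum(axis=0) - mean1.sum(axis=0)
        hess = -(
            (s2 / s0[:, None, None]).sum(axis=0)
            - np.einsum("ij,ik->jk", mean1, mean1)
        )
        return ll, grad, hess

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for tk in np.unique(t_ev):
        D = ev[t_ev == tk]
        d = len(D)
        i0 = np.searchsorted(t, tk, side="left")  # first index in the risk set
        s0, s1, s2 = S0[i0], S1[i0], S2[i0]
        d0 = theta[D].sum()
        d1 = Xw[D].sum(axis=0)
        d2 = XX[D].sum(axis=0)
        ll += float(eta[D].sum())
        for ell in range(d):
            f = ell / d
            den = s0 - f * d0
            nu = (s1 - f * d1) / den
            ll -= np.log(den)
            grad_term = nu
            grad -= grad_term
            hess -= (s2 - f * d2) / den - np.outer(nu, nu)
        grad += X[D].sum(axis=0)
    return ll, grad, hess


def cox_loglik(beta, covariates, survival: pd.DataFrame) -> float:
    """Efron partial log-likelihood at an arbitrary coefficient vector."""
    X, t, e = _prepare(covariates, survival)
    order = np.argsort(t, kind="stable")
    Xs = X.to_numpy(dtype=float)[order]
    ll, _, _ = _efron_quantities(np.asarray(beta, dtype=float), Xs, t[order], e[order])
    return ll


def cox_fit(
    covariates,
    survival: pd.DataFrame,
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxFitResult:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    covariates
        DataFrame (or Series / array) of explanatory variables indexed like
        ``survival``.  Rows with any missing covariate are dropped
        (complete-case analysis).
    survival
        Table with ``time_months`` and ``event`` columns.

    Raises
    ------
    CoxError
        If there are no events, a covariate has no variation, the information
        matrix is singular, or Newton iteration fails to converge.
    """
    X, t, e = _prepare(covariates, survival)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if n == 0:
        raise CoxError("no complete cases")
    if e.sum() == 0:
        raise CoxError("zero events: the partial likelihood is flat")
    sd = Xv.std(axis=0)
    flat = [names[j] for j in range(p) if sd[j] == 0]
    if flat:
        raise CoxError(f"no variation in covariate(s): {flat}")

    # centre covariates for conditioning; the partial likelihood is invariant
    centre = Xv.mean(axis=0)
    Xc = Xv - centre
    order = np.argsort(t, kind="stable")
    Xs, ts, es = Xc[order], t[order], e[order]

    beta = np.zeros(p)
    ll, grad, hess = _efron_quantities(beta, Xs, ts, es)
    ll0, score0, info0 = ll, grad.copy(), -hess.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # tolerance scaled by the log-likelihood magnitude: float cancellation
        # in the risk-set cumsums bounds the attainable gradient norm
        if np.linalg.norm(grad) < tol * max(1.0, abs(ll)):
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxError("singular information matrix (collinear covariates?)") from exc
        if not np.all(np.isfinite(step)):
            raise CoxError("singular information matrix (collinear covariates?)")
        if np.linalg.norm(step) < 1e-10 * (1.0 + np.linalg.norm(beta)):
            break  # at float resolution of the optimum
        # step-halving line search; acceptance band scaled like the loglik
        slack = 1e-9 * max(1.0, abs(ll))
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, hess_new = _efron_quantities(cand, Xs, ts, es)
            if np.isfinite(ll_new) and ll_new >= ll - slack:
                break
            factor *= 0.5
        else:
            raise CoxError("Cox Newton iteration failed to make progress")
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
    else:
        raise CoxError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(|grad| = {np.linalg.norm(grad):.3g})"
        )

    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise CoxError("singular information matrix at the optimum") from exc
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(se)):
        raise CoxError("non-finite standard errors (degenerate fit)")
    return CoxFitResult(
        covariates=names,
        coefficients=beta,
        standard_errors=se,
        log_likelihood=float(ll),
        log_likelihood_null=float(ll0),
        n=n,
        n_events=int(e.sum()),
        n_iter=n_iter,
        score_at_zero=score0,
        information_at_zero=info0,
    )


def logrank(groups, survival: pd.DataFrame) -> LogRankResult:
    """Log-rank test comparing survival between two or more groups.

    ``groups`` is a label per patient aligned with ``survival``.  The
    chi-square statistic uses the hypergeometric variance of the observed
    event counts over distinct event times; with G groups the statistic is
    quadratic in the first G−1 components of O − E, df = G − 1.
    """
    if isinstance(groups, pd.Series):
        g = groups.reindex(survival.index)
    else:
        g = pd.Series(np.asarray(groups), index=survival.index)
    keep = g.notna()
    g = g.loc[keep]
    t = survival.loc[keep, "time_months"].to_numpy(dtype=float)
    e = survival.loc[keep, "event"].to_numpy(dtype=int)
    labels = sorted(pd.unique(g))
    G = len(labels)
    if G < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    if e.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    gi = g.map({lab: i for i, lab in enumerate(labels)}).to_numpy()

    event_times = np.unique(t[e == 1])
    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    for tk in event_times:
        at_risk = t >= tk
        n_k = at_risk.sum()
        d_k = int(((t == tk) & (e == 1)).sum())
        n_gk = np.bincount(gi[at_risk], minlength=G).astype(float)
        d_gk = np.bincount(gi[(t == tk) & (e == 1)], minlength=G).astype(float)
        O += d_gk
        E += d_k * n_gk / n_k
        if n_k > 1:
            frac = n_gk / n_k
            mult = d_k * (n_k - d_k) / (n_k - 1)
            V += mult * (np.diag(frac) - np.outer(frac, frac))
    U = (O - E)[: G - 1]
    Vsub = V[: G - 1, : G - 1]
    try:
        chi2 = float(U @ np.linalg.solve(Vsub, U))
    except np.linalg.LinAlgError:
        chi2 = float(U @ np.linalg.pinv(Vsub) @ U)
    chi2 = max(chi2, 0.0)
    df = G - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(
        chi_square=chi2, df=df, p=p, groups=labels, observed=O, expected=E
    )


def deviance_compare(full: CoxFitResult, reduced: CoxFitResult | None):
    """Likelihood-ratio (analysis of deviance) comparison of nested Cox models.

    ``reduced=None`` compares against the empty (null) model.  Returns
    ``(lrt_statistic, df, p)`` with the statistic clipped at zero.
    """
    if reduced is None:
        ll_r, k_r = full.log_likelihood_null, 0
        n_r, e_r = full.n, full.n_events
    else:
        if not set(reduced.covariates) <= set(full.covariates):
            raise ValueError(
                "models are not nested: reduced covariates "
                f"{reduced.covariates} not a subset of {full.covariates}"
            )
        if (reduced.n, reduced.n_events) != (full.n, full.n_events):
            raise ValueError(
                "models were fitted on different samples; harmonise complete "
                "cases before fitting both"
            )
        ll_r, k_r = reduced.log_likelihood, len(reduced.covariates)
        n_r, e_r = reduced.n, reduced.n_events
    df = len(full.covariates) - k_r
    if df < 0:
        raise ValueError("full model has fewer parameters than the reduced model")
    stat = max(0.0, 2.0 * (full.log_likelihood - ll_r))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


class KaplanMeierCurve:
    """Product-limit survival estimate, queryable at any non-negative time."""

    def __init__(self, times: np.ndarray, survival: np.ndarray, variance: np.ndarray):
        self.event_times = times
        self.survival_probs = survival
        self.greenwood_variance = variance

    def at(self, t) -> np.ndarray | float:
        """S(t): right-continuous step function, S(t) = 1 before the first event."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival queried at negative time")
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival_probs])[idx]
        return float(s) if s.ndim == 0 else s

    def restricted_mean(self, horizon: float) -> float:
        """Area under S(t) on [0, horizon]."""
        knots = np.concatenate([[0.0], self.event_times, [horizon]])
        knots = np.clip(knots, 0, horizon)
        vals = np.concatenate([[1.0], self.survival_probs, [self.at(horizon)]])
        return float(np.sum(np.diff(knots) * vals[:-1]))


def kaplan_meier(survival: pd.DataFrame, group=None) -> KaplanMeierCurve:
    """Kaplan-Meier estimator, optionally restricted to one group's rows.

    ``group`` may be a boolean mask aligned with ``survival``.
    """
    df = survival if group is None else survival.loc[np.asarray(group, dtype=bool)]
    if len(df) == 0:
        raise ValueError("empty survival table")
    t = df["time_months"].to_numpy(dtype=float)
    e = df["event"].to_numpy(dtype=int)
    event_times = np.unique(t[e == 1])
    surv = []
    var_terms = []
    s = 1.0
    acc = 0.0
    for tk in event_times:
        n_k = int((t >= tk).sum())
        d_k = int(((t == tk) & (e == 1)).sum())
        s *= 1.0 - d_k / n_k
        if n_k > d_k:
            acc += d_k / (n_k * (n_k - d_k))
        surv.append(s)
        var_terms.append(s * s * acc)
    return KaplanMeierCurve(
        event_times, np.asarray(surv, dtype=float), np.asarray(var_terms, dtype=float)
    )
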