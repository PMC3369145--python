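"""Transition-stratified Cox regression on clock-reset (sojourn) time.

Transition hazards are modelled by a Cox proportional-hazards model
stratified on transitions, with transition-specific covariates (sex and
age), on the semi-Markov time scale: the clock is reset to zero each time a
patient enters a new state, so the hazard of a q→r move depends on time
spent in q, not on time since the first arthroplasty.

Because every stratum (transition) has its own covariate coefficients, the
stratified partial likelihood is a product of per-stratum partial
likelihoods with disjoint parameters; the joint maximizer is therefore the
collection of per-transition maximizers.  This module exploits that
factorization and fits each transition separately with Newton-Raphson on
the Efron-tie-corrected partial likelihood.  On the clock-reset scale every
at-risk interval starts at 0, so each per-transition fit is an ordinary
right-censored Cox fit on the sojourn durations.

Proportionality is checked per transition with Schoenfeld residuals and the
Grambsch-Therneau score test of zero slope of the scaled residuals against
(by default) identity-transformed event time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxResult",
    "TransitionCoxFit",
    "SchoenfeldDiagnostics",
    "coxph",
    "fit_transition_cox",
    "schoenfeld_residuals",
    "schoenfeld_test",
    "hazard_ratio_table",
]

MAX_ITER = 50
GRAD_TOL = 1e-8
#: |beta| beyond which a still-unconverged fit is flagged as monotone
#: likelihood (perfect separation): HR > e^15 has no finite MLE in practice
MONOTONE_BETA = 15.0


@dataclass
class CoxResult:
    """One proportional-hazards fit: estimates, inference, convergence."""

    covariates: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    iterations: int
    gradient_norm: float
    converged: bool
    monotone: bool = False
    information: np.ndarray | None = None

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Wald CI for the hazard ratios, shape (p, 2)."""
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.beta - z * self.se)
        hi = np.exp(self.beta + z * self.se)
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.beta / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "term": self.covariates,
                "beta": self.beta,
                "se": self.se,
                "HR": self.hazard_ratios,
                "ci_lo": ci[:, 0],
                "ci_hi": ci[:, 1],
                "p": self.p_values,
            }
        )


def _efron_quantities(beta, t, X, order, starts, event_lists):
    """Log partial likelihood, gradient and negative Hessian (Efron ties).

    ``order`` sorts times ascending; ``starts[k]`` is the first index (in the
    ascending sort) of the risk set for the k-th distinct event time (all
    subjects with t >= t_k); ``event_lists[k]`` indexes the tied events.
    """
    n, p = X.shape
    eta = X @ beta
    # cap to avoid overflow during monotone-likelihood excursions
    r = np.exp(np.clip(eta, -700, 700))
    Xs = X[order]
    rs = r[order]
    # suffix sums: S0[i] = sum_{j >= i} r, S1[i] = sum_{j >= i} r x
    S0 = np.cumsum(rs[::-1])[::-1]
    S1 = np.cumsum((rs[:, None] * Xs)[::-1], axis=0)[::-1]
    # S2 as flattened outer products (p small)
    xx = Xs[:, :, None] * Xs[:, None, :]
    S2 = np.cumsum((rs[:, None, None] * xx)[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for k, ev_idx in enumerate(event_lists):
        i0 = starts[k]
        dk = len(ev_idx)
        s0g, s1g, s2g = S0[i0], S1[i0], S2[i0]
        re = r[ev_idx]
        Xe = X[ev_idx]
        s0d = re.sum()
        s1d = (re[:, None] * Xe).sum(axis=0)
        s2d = (re[:, None, None] * (Xe[:, :, None] * Xe[:, None, :])).sum(axis=0)
        loglik += eta[ev_idx].sum()
        grad += Xe.sum(axis=0)
        frac = np.arange(dk) / dk
        for f in frac:
            den = s0g - f * s0d
            num1 = s1g - f * s1d
            num2 = s2g - f * s2d
            loglik -= np.log(den)
            xbar = num1 / den
            grad -= xbar
            info += num2 / den - np.outer(xbar, xbar)
    return loglik, grad, info


def _risk_structure(t, status):
    order = np.argsort(t, kind="stable")
    t_sorted = t[order]
    ev_mask = status == 1
    event_times = np.unique(t[ev_mask])
    starts = np.searchsorted(t_sorted, event_times, side="left")
    event_lists = []
    all_ev_idx = np.flatnonzero(ev_mask)
    ev_t = t[all_ev_idx]
    for tk in event_times:
        event_lists.append(all_ev_idx[ev_t == tk])
    return order, starts, event_lists, event_times


def coxph(
    durations: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    covariates: tuple[str, ...] | None = None,
    max_iter: int = MAX_ITER,
    tol: float = GRAD_TOL,
) -> CoxResult:
    """Maximize the Cox partial likelihood (Efron tie correction).

    Newton-Raphson from beta = 0, with step-halving if the log partial
    likelihood decreases.  Convergence when the max |gradient| < ``tol``.
    A monotone (perfectly separating) likelihood is detected by the estimate
    escaping past ``MONOTONE_BETA`` and flagged rather than raised.
    """
    t = np.asarray(durations, float)
    d = np.asarray(events, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != t.shape[0]:
        X = X.T
    n, p = X.shape
    if covariates is None:
        covariates = tuple(f"x{j}" for j in range(p))
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError("no events: partial likelihood is constant")

    order, starts, event_lists, _ = _risk_structure(t, d)
    beta = np.zeros(p)
    ll, grad, info = _efron_quantities(beta, t, X, order, starts, event_lists)
    iterations = 0
    monotone = False
    for iterations in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            monotone = True
            break
        new_beta = beta + step
        new_ll, new_grad, new_info = _efron_quantities(
            new_beta, t, X, order, starts, event_lists
        )
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step /= 2.0
            halvings += 1
            if halvings > 30:
                break
            new_beta = beta + step
            new_ll, new_grad, new_info = _efron_quantities(
                new_beta, t, X, order, starts, event_lists
            )
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.max(np.abs(grad)) < tol:
            break
        if np.max(np.abs(beta)) > MONOTONE_BETA:
            monotone = True
            break
    converged = np.max(np.abs(grad)) < tol and not monotone
    if monotone:
        warnings.warn(
            "monotone partial likelihood (perfect separation): estimate has "
            "no finite maximum; fit flagged as non-converged"
        )
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    return CoxResult(
        covariates=tuple(covariates),
        beta=beta,
        se=se,
        loglik=float(ll),
        n=n,
        n_events=n_events,
        iterations=iterations,
        gradient_norm=float(np.max(np.abs(grad))),
        converged=bool(converged),
        monotone=monotone,
        information=info,
    )


@dataclass
class TransitionCoxFit:
    """Per-transition Cox fits from one stratified model."""

    covariates: tuple[str, ...]
    fits: dict[tuple[int, int], CoxResult]
    skipped: dict[tuple[int, int], str] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        frames = []
        for (q, r), res in sorted(self.fits.items()):
            s = res.summary()
            s.insert(0, "transition", f"{q}->{r}")
            s["n_events"] = res.n_events
            s["converged"] = res.converged
            frames.append(s)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)


def fit_transition_cox(
    rows: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "age"),
    timescale: str = "clock_reset",
    transitions: list[tuple[int, int]] | None = None,
) -> TransitionCoxFit:
    """Fit the transition-stratified Cox model, one fit per transition.

    ``rows`` is the long-format frame from ``to_transition_rows``.  With
    transition-specific covariates the stratified partial likelihood
    factorizes over transitions, so the per-transition fits ARE the
    stratified fit.  Transitions with no events are skipped with a notice;
    transitions whose covariates are constant over the at-risk rows cannot
    be fit and are likewise skipped.
    """
    fits: dict[tuple[int, int], CoxResult] = {}
    skipped: dict[tuple[int, int], str] = {}
    pairs = transitions or sorted(
        rows[["from", "to"]].drop_duplicates().itertuples(index=False, name=None)
    )
    for q, r in pairs:
        sub = rows[(rows["from"] == q) & (rows["to"] == r)]
        if sub.empty:
            skipped[(q, r)] = "no at-risk rows"
            continue
        n_ev = int(sub["status"].sum())
        if n_ev == 0:
            skipped[(q, r)] = "no events"
            continue
        if timescale == "clock_reset":
            t = sub["duration"].to_numpy(float)
        elif timescale == "clock_forward":
            # delayed entry is not supported; clock-forward fits require
            # Tstart == 0 for all rows (true only out of the initial state)
            if (sub["Tstart"] > 0).any():
                skipped[(q, r)] = "clock_forward with delayed entry unsupported"
                continue
            t = sub["Tstop"].to_numpy(float)
        else:
            raise ValueError(f"unknown timescale {timescale!r}")
        X = sub[list(covariates)].to_numpy(float)
        if np.any(X.std(axis=0) == 0):
            skipped[(q, r)] = "constant covariate"
            continue
        fits[(q, r)] = coxph(t, sub["status"].to_numpy(int), X, covariates)
    for pair, why in skipped.items():
        warnings.warn(f"transition {pair[0]}->{pair[1]} skipped: {why}")
    return TransitionCoxFit(covariates=tuple(covariates), fits=fits, skipped=skipped)


@dataclass(frozen=True)
class SchoenfeldDiagnostics:
    """Schoenfeld residuals and the Grambsch-Therneau PH test."""

    covariates: tuple[str, ...]
    event_times: np.ndarray  # one per event (tied events repeat the time)
    residuals: np.ndarray  # (n_events, p)
    scaled_residuals: np.ndarray  # (n_events, p)
    statistic: np.ndarray  # chi-square, per covariate
    p_value: np.ndarray


def schoenfeld_residuals(
    durations: np.ndarray, events: np.ndarray, X: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Efron-consistent Schoenfeld residuals at beta.

    For each event, the covariate of the failing subject minus the risk-set
    weighted mean; within a tied group the mean averages the Efron-adjusted
    denominators, so that the residuals sum to the score (zero at the MLE).
    Returns (event_times, residuals), events in time order.
    """
    t = np.asarray(durations, float)
    d = np.asarray(events, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != t.shape[0]:
        X = X.T
    order, starts, event_lists, event_times = _risk_structure(t, d)
    r = np.exp(np.clip(X @ beta, -700, 700))
    Xs, rs = X[order], r[order]
    S0 = np.cumsum(rs[::-1])[::-1]
    S1 = np.cumsum((rs[:, None] * Xs)[::-1], axis=0)[::-1]
    times_out, resid_out = [], []
    for k, ev_idx in enumerate(event_lists):
        i0 = starts[k]
        dk = len(ev_idx)
        re, Xe = r[ev_idx], X[ev_idx]
        s0d = re.sum()
        s1d = (re[:, None] * Xe).sum(axis=0)
        xbar = np.zeros(X.shape[1])
        for f in np.arange(dk) / dk:
            xbar += (S1[i0] - f * s1d) / (S0[i0] - f * s0d)
        xbar /= dk
        for i in ev_idx:
            times_out.append(t[i])
            resid_out.append(X[i] - xbar)
    return np.array(times_out), np.array(resid_out)


def schoenfeld_test(
    fit: CoxResult,
    durations: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    time_transform: str = "identity",
) -> SchoenfeldDiagnostics | None:
    """Grambsch-Therneau score test for proportional hazards.

    Tests zero slope of the scaled Schoenfeld residuals against transformed
    event time; a small p-value indicates a time-varying effect.  With fewer
    than two events the diagnostic is undefined and ``None`` is returned.
    ``time_transform``: "identity" (clock-reset duration, the default) or
    "rank" (rank of the event time).
    """
    t = np.asarray(durations, float)
    d = np.asarray(events, int)
    n_ev = int(d.sum())
    if n_ev < 2:
        return None
    times, resid = schoenfeld_residuals(t, d, X, fit.beta)
    if time_transform == "identity":
        g = times.astype(float)
    elif time_transform == "rank":
        g = stats.rankdata(times).astype(float)
    else:
        raise ValueError(f"unknown time transform {time_transform!r}")
    g_c = g - g.mean()
    V_bar = fit.information / n_ev  # average per-event information
    V_inv = np.linalg.inv(V_bar)
    scaled = resid @ V_inv + fit.beta  # Grambsch-Therneau scaling
    u = g_c @ resid  # (p,)
    gsq = float(np.sum(g_c**2))
    # per-covariate score statistic against transformed time; chi2, 1 df
    stat = (V_inv @ u) ** 2 / (np.diag(V_inv) * gsq)
    p = stats.chi2.sf(stat, df=1)
    return SchoenfeldDiagnostics(
        covariates=fit.covariates,
        event_times=times,
        residuals=resid,
        scaled_residuals=scaled,
        statistic=stat,
        p_value=p,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "a"
    if p < 0.01:
        return "b"
    if p < 0.05:
        return "c"
    return ""


def hazard_ratio_table(
    fits_by_group: dict[str, TransitionCoxFit],
    term: str = "sex",
) -> pd.DataFrame:
    """Formatted per-transition, per-group hazard-ratio table for one term.

    Rows keyed "q->r"; per group the HR (e.g. male/female, adjusted for the
    other covariates), its 95% Wald CI and significance stars
    (a: p<0.001, b: p<0.01, c: p<0.05).  Transitions a group could not fit
    are marked not estimable.
    """
    all_pairs = sorted(
        {pair for f in fits_by_group.values() for pair in (*f.fits, *f.skipped)}
    )
    records = []
    for q, r in all_pairs:
        row: dict[str, object] = {"transition": f"{q}->{r}"}
        for g, tf in fits_by_group.items():
            res = tf.fits.get((q, r))
            if res is None or not res.converged:
                row[f"{g}_HR"] = np.nan
                row[f"{g}_CI"] = "not estimable"
                continue
            j = res.covariates.index(term)
            ci = res.conf_int()[j]
            p = res.p_values[j]
            row[f"{g}_HR"] = round(float(res.hazard_ratios[j]), 2)
            row[f"{g}_CI"] = f"{ci[0]:.2f}-{ci[1]:.2f}{_stars(p)}"
        records.append(row)
    return pd.DataFrame(records).set_index("transition")
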