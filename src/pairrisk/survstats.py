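"""Survival and group-comparison statistics for prognostic screening.

Everything here operates on right-censored overall-survival data
(``times`` > 0, ``events`` in {0, 1} with 1 = death observed).  The
screening stages fit thousands of single-covariate models against one
shared survival outcome, so the workhorses (log-rank, Gehan-Wilcoxon,
Cox with a binary covariate) come in ``*_many`` forms vectorised over a
stack of binary covariates; the scalar entry points delegate to them.

Conventions fixed here and relied on by the tests:

* subjects censored exactly at an event time are counted at risk at that
  time (the usual product-limit convention);
* tied event times in the Cox partial likelihood are handled with the
  Efron correction;
* the "Wilcoxon" survival test is the Gehan-Breslow generalised
  Wilcoxon, i.e. the log-rank O/E tabulation weighted by the number at
  risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalData",
    "CoxFit",
    "KmCurve",
    "TdRocCurve",
    "km_estimate",
    "km_survival_at",
    "logrank",
    "multigroup_logrank",
    "gehan_wilcoxon",
    "cox_binary",
    "cox_binary_many",
    "logrank_many",
    "gehan_wilcoxon_many",
    "td_roc",
    "welch_t",
    "paired_t",
]

_BETA_CAP = 20.0
_NEWTON_TOL = 1e-8
_NEWTON_MAXITER = 100


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival outcome, optionally with a binary group."""

    times: np.ndarray
    events: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events)
        if times.ndim != 1 or events.shape != times.shape:
            raise ValueError("times and events must be 1-d and equally long")
        if np.any(times <= 0) or not np.all(np.isfinite(times)):
            raise ValueError("survival times must be positive and finite")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("events must be 0/1")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events.astype(np.int8))
        if self.group is not None:
            group = np.asarray(self.group)
            if group.shape != times.shape:
                raise ValueError("group must match times in length")
            object.__setattr__(self, "group", group)

    def __len__(self) -> int:
        return self.times.shape[0]


@dataclass(frozen=True)
class CoxFit:
    """Single-covariate Cox fit: log hazard ratio and Wald inference."""

    beta: float
    hr: float
    se: float
    p_wald: float
    converged: bool
    n_events: int


@dataclass(frozen=True)
class KmCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass(frozen=True)
class TdRocCurve:
    """Cumulative-case / dynamic-control ROC at a fixed horizon."""

    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float


# ---------------------------------------------------------------------------
# risk-set tabulation shared by every rank-type statistic


def _risk_table(times: np.ndarray, events: np.ndarray):
    """Counts at each distinct event time.

    Returns ``(event_times, d, n, order, n_idx)`` where ``d``/``n`` are
    deaths and numbers at risk, ``order`` sorts subjects by time and
    ``n_idx[k]`` is the first position (in sorted order) belonging to
    the k-th risk set — suffix sums over ``order`` evaluated at
    ``n_idx`` give per-group at-risk counts.
    """
    order = np.argsort(times, kind="stable")
    ts = times[order]
    es = events[order]
    event_times = np.unique(ts[es == 1])
    n_idx = np.searchsorted(ts, event_times, side="left")
    n = times.shape[0] - n_idx
    # deaths at each distinct event time
    death_pos = np.searchsorted(event_times, ts[es == 1])
    d = np.bincount(death_pos, minlength=event_times.shape[0])
    return event_times, d, n, order, n_idx


def _group_counts(Z: np.ndarray, times: np.ndarray, events: np.ndarray,
                  order: np.ndarray, n_idx: np.ndarray, event_times: np.ndarray):
    """Per-covariate at-risk and death counts in the z=1 group.

    ``Z`` is (G, n) of 0/1.  Returns ``n1`` and ``d1`` with shape
    (G, K) over the K distinct event times.
    """
    Zs = Z[:, order].astype(float)
    # suffix sums: number of z=1 subjects with time >= event_times[k]
    suffix = np.concatenate(
        [np.cumsum(Zs[:, ::-1], axis=1)[:, ::-1], np.zeros((Z.shape[0], 1))], axis=1
    )
    n1 = suffix[:, n_idx]
    es = events[order]
    ts = times[order]
    death_mask = es == 1
    death_pos = np.searchsorted(event_times, ts[death_mask])
    K = event_times.shape[0]
    G = Z.shape[0]
    d1 = np.zeros((G, K))
    np.add.at(d1.T, death_pos, Zs[:, death_mask].T)
    return n1, d1


# ---------------------------------------------------------------------------
# Kaplan-Meier


def km_estimate(data: SurvivalData) -> KmCurve:
    """Product-limit survival estimate.

    All-censored input yields an empty event grid (S identically 1).
    """
    if len(data) < 1:
        raise ValueError("need at least one record")
    event_times, d, n, _, _ = _risk_table(data.times, data.events)
    with np.errstate(divide="ignore"):
        survival = np.cumprod(1.0 - d / n)
    return KmCurve(event_times=event_times, survival=survival, at_risk=n)


def km_survival_at(curve: KmCurve, t: float) -> float:
    """Step-function evaluation S(t) of a product-limit curve."""
    idx = np.searchsorted(curve.event_times, t, side="right")
    return 1.0 if idx == 0 else float(curve.survival[idx - 1])


# ---------------------------------------------------------------------------
# rank tests


def _weighted_oe(times, events, Z, weights_fn):
    event_times, d, n, order, n_idx = _risk_table(times, events)
    if event_times.shape[0] == 0:
        raise ValueError("no events observed")
    n1, d1 = _group_counts(Z, times, events, order, n_idx, event_times)
    w = weights_fn(n)
    frac = n1 / n
    U = np.sum(w * (d1 - d * frac), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_t = d * frac * (1.0 - frac) * np.where(n > 1, (n - d) / (n - 1.0), 0.0)
    V = np.sum(w * w * v_t, axis=1)
    return U, V


def _chi2_from_uv(U, V):
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(V > 0, U * U / np.where(V > 0, V, 1.0), 0.0)
    p = stats.chi2.sf(chi2, df=1)
    return chi2, np.clip(p, np.finfo(float).tiny, 1.0)


def logrank_many(times, events, Z) -> tuple[np.ndarray, np.ndarray]:
    """Two-group log-rank statistics for a (G, n) stack of 0/1 covariates."""
    U, V = _weighted_oe(times, events, np.asarray(Z), lambda n: np.ones_like(n, dtype=float))
    return _chi2_from_uv(U, V)


def gehan_wilcoxon_many(times, events, Z) -> tuple[np.ndarray, np.ndarray]:
    """Gehan-Breslow statistics (weight = n at risk) for a covariate stack."""
    U, V = _weighted_oe(times, events, np.asarray(Z), lambda n: n.astype(float))
    return _chi2_from_uv(U, V)


def _two_group_check(data: SurvivalData):
    if data.group is None:
        raise ValueError("two-group test needs a group indicator")
    g = np.asarray(data.group)
    levels = np.unique(g)
    if levels.shape[0] != 2:
        raise ValueError(f"need exactly two groups, found {levels.shape[0]}")
    return (g == levels[1]).astype(np.int8)


def logrank(data: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) on 1 df."""
    z = _two_group_check(data)
    chi2, p = logrank_many(data.times, data.events, z[None, :])
    return float(chi2[0]), float(p[0])


def gehan_wilcoxon(data: SurvivalData) -> tuple[float, float]:
    """Gehan-Breslow generalised Wilcoxon test; returns (chi2, p)."""
    z = _two_group_check(data)
    chi2, p = gehan_wilcoxon_many(data.times, data.events, z[None, :])
    return float(chi2[0]), float(p[0])


def multigroup_logrank(times, events, labels) -> tuple[float, float, int]:
    """k-sample log-rank test; returns (chi2, p, df) with df = k - 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    k = levels.shape[0]
    if k < 2:
        raise ValueError("need at least two groups")
    event_times, d, n, order, n_idx = _risk_table(times, events)
    if event_times.shape[0] == 0:
        raise ValueError("no events observed")
    Z = (labels[None, :] == levels[:, None]).astype(np.int8)
    n_i, d_i = _group_counts(Z, times, events, order, n_idx, event_times)
    frac = n_i / n  # (k, K)
    O_minus_E = np.sum(d_i - d * frac, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = d * np.where(n > 1, (n - d) / (n - 1.0), 0.0)
    V = np.einsum("k,ik,jk->ij", scale, frac, -frac)
    V[np.diag_indices(k)] += np.sum(scale * frac * (1.0 - frac), axis=1) + np.sum(
        scale * frac * frac, axis=1
    )
    x = O_minus_E[:-1]
    Vr = V[:-1, :-1]
    chi2 = float(x @ np.linalg.pinv(Vr) @ x)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, max(p, np.finfo(float).tiny), k - 1


# ---------------------------------------------------------------------------
# Cox partial likelihood, binary covariate, Efron ties


def _efron_design(times, events, Z):
    """Per-(event time, tie index) coefficients of the Efron likelihood.

    For a binary covariate the Efron partial log-likelihood is

        ll(beta) = d1_tot * beta - sum_{k,l} log(a_{kl} + b_{kl} e^beta)

    with, at event time k holding d deaths (d1 of them in group 1) and a
    risk set of n (n1 in group 1),

        a_{kl} = (n - n1) - (l/d) (d - d1),   b_{kl} = n1 - (l/d) d1

    for l = 0..d-1.  Returns (a, b, d1_tot), each of shape (G, D) where
    D is the total number of events.
    """
    event_times, d, n, order, n_idx = _risk_table(times, events)
    if event_times.shape[0] == 0:
        raise ValueError("no events observed")
    n1, d1 = _group_counts(Z, times, events, order, n_idx, event_times)
    reps = d.astype(int)
    l_over_d = np.concatenate([np.arange(di) / di for di in reps])
    n_rep = np.repeat(n, reps).astype(float)
    d_rep = np.repeat(d, reps).astype(float)
    n1_rep = np.repeat(n1, reps, axis=1)
    d1_rep = np.repeat(d1, reps, axis=1)
    a = (n_rep - n1_rep) - l_over_d * (d_rep - d1_rep)
    b = n1_rep - l_over_d * d1_rep
    d1_tot = np.sum(d1, axis=1)
    return a, b, d1_tot


def cox_binary_many(times, events, Z):
    """Efron-tie Cox fits for a (G, n) stack of binary covariates.

    Safeguarded Newton iteration from beta = 0 (the likelihood is
    concave in beta, so clipped Newton steps converge); fits that run
    into separation are capped at |beta| = 20 and flagged.

    Returns dict of arrays: beta, hr, se, p_wald, converged, n_events.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    Z = np.asarray(Z)
    a, b, d1_tot = _efron_design(times, events, Z)
    G = Z.shape[0]
    beta = np.zeros(G)
    active = np.ones(G, dtype=bool)
    converged = np.zeros(G, dtype=bool)
    for _ in range(_NEWTON_MAXITER):
        if not active.any():
            break
        r = np.exp(beta[active])[:, None]
        denom = a[active] + b[active] * r
        br = b[active] * r
        score = d1_tot[active] - np.sum(br / denom, axis=1)
        info = np.sum(a[active] * br / (denom * denom), axis=1)
        step = np.where(info > 0, score / np.where(info > 0, info, 1.0), 0.0)
        step = np.clip(step, -2.0, 2.0)
        new = np.clip(beta[active] + step, -_BETA_CAP, _BETA_CAP)
        moved = np.abs(new - beta[active])
        beta[active] = new
        done = (moved < _NEWTON_TOL) | (np.abs(new) >= _BETA_CAP)
        idx = np.flatnonzero(active)
        converged[idx[done & (np.abs(new) < _BETA_CAP)]] = True
        active[idx[done]] = False
    r = np.exp(beta)[:, None]
    denom = a + b * r
    info = np.sum(a * b * r / (denom * denom), axis=1)
    with np.errstate(divide="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.where(info > 0, info, 1.0)), np.inf)
    with np.errstate(invalid="ignore"):
        zstat = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    p_wald = np.clip(2.0 * stats.norm.sf(np.abs(zstat)), np.finfo(float).tiny, 1.0)
    n_events = int(np.sum(events))
    return {
        "beta": beta,
        "hr": np.exp(beta),
        "se": se,
        "p_wald": p_wald,
        "converged": converged,
        "n_events": np.full(G, n_events),
    }


def cox_binary(data: SurvivalData) -> CoxFit:
    """Univariable Cox fit of a binary group indicator (Efron ties)."""
    z = _two_group_check(data)
    if data.events.sum() == 0:
        raise ValueError("no events observed")
    out = cox_binary_many(data.times, data.events, z[None, :])
    return CoxFit(
        beta=float(out["beta"][0]),
        hr=float(out["hr"][0]),
        se=float(out["se"][0]),
        p_wald=float(out["p_wald"][0]),
        converged=bool(out["converged"][0]),
        n_events=int(out["n_events"][0]),
    )


# ---------------------------------------------------------------------------
# time-dependent ROC (cumulative cases / dynamic controls)


def td_roc(marker, data: SurvivalData, horizon: float) -> TdRocCurve:
    """Cumulative-case / dynamic-control ROC at ``horizon``.

    Case and control probabilities are estimated with Kaplan-Meier
    curves fit inside the marker-defined subsets (Heagerty-style "KM"
    estimator): for a cutoff c, with p_c = P(M > c),

        Sens(c) = (1 - S(horizon | M > c)) p_c / (1 - S(horizon))
        1-Spec(c) = S(horizon | M > c) p_c / S(horizon).

    Each distinct marker value is one threshold.  The raw subset-KM
    estimator is not guaranteed monotone under censoring, so the
    assembled curve is made monotone with a running maximum before the
    trapezoidal AUC is taken; without censoring before the horizon the
    estimator is exactly the empirical ROC and the running maximum is a
    no-op.
    """
    marker = np.asarray(marker, dtype=float)
    if marker.shape[0] != len(data):
        raise ValueError("marker length must match survival data")
    if not np.all(np.isfinite(marker)):
        raise ValueError("marker must be finite")
    s_tau = km_survival_at(km_estimate(data), horizon)
    if s_tau >= 1.0:
        raise ValueError("no cases by the horizon (S(horizon) = 1)")
    if s_tau <= 0.0:
        raise ValueError("no controls at the horizon (S(horizon) = 0)")
    thresholds = np.unique(marker)[::-1]  # descending: strictest first
    n = marker.shape[0]
    sens = np.empty(thresholds.shape[0])
    fpr = np.empty(thresholds.shape[0])
    for i, c in enumerate(thresholds):
        mask = marker >= c  # classify positive at value >= c
        p_c = mask.mean()
        sub = SurvivalData(times=data.times[mask], events=data.events[mask])
        s_sub = km_survival_at(km_estimate(sub), horizon)
        sens[i] = (1.0 - s_sub) * p_c / (1.0 - s_tau)
        fpr[i] = s_sub * p_c / s_tau
    sens = np.clip(sens, 0.0, 1.0)
    fpr = np.clip(fpr, 0.0, 1.0)
    sens = np.maximum.accumulate(sens)
    fpr = np.maximum.accumulate(fpr)
    sens_full = np.concatenate([[0.0], sens, [1.0]])
    fpr_full = np.concatenate([[0.0], fpr, [1.0]])
    auc = float(np.trapezoid(sens_full, fpr_full))
    return TdRocCurve(
        horizon=float(horizon),
        thresholds=thresholds,
        sensitivity=sens,
        one_minus_specificity=fpr,
        auc=auc,
    )


# ---------------------------------------------------------------------------
# t tests (scipy-backed, with explicit degenerate-input behaviour)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, p) two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 2 or y.shape[0] < 2:
        raise ValueError("each group needs at least two observations")
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:  # both groups constant
        if x[0] == y[0]:
            return 0.0, float(x.shape[0] + y.shape[0] - 2), 1.0
        return float(np.sign(np.mean(x) - np.mean(y)) * 1e6), float(
            x.shape[0] + y.shape[0] - 2
        ), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t-test on x - y; returns (t, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.shape[0] < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    diff = x - y
    if np.allclose(np.var(diff, ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        # constant nonzero shift: statistic diverges, cap it
        return float(np.sign(diff.mean()) * 1e6), 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
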