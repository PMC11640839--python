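"""Independent brute-force oracles used to verify the survival statistics.

Everything here is written as plain loops straight from the defining
formulas, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def km_oracle(times, events):
    """Product-limit estimate by direct tabulation: {event time: S(t)}."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n
        out[t] = s
    return out


def weighted_logrank_oracle(times, events, z, gehan=False):
    """Two-group (weighted) log-rank chi-square by per-event-time O/E/V."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    z = np.asarray(z)
    U = 0.0
    V = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (z == 1)).sum())
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        d1 = int((dead & (z == 1)).sum())
        w = n if gehan else 1.0
        U += w * (d1 - d * n1 / n)
        if n > 1:
            V += w * w * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (U * U / V) if V > 0 else 0.0


def efron_loglik(beta, times, events, z):
    """Efron-corrected partial log-likelihood for one binary covariate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    z = np.asarray(z)
    r = np.exp(beta)
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        d1 = int((dead & (z == 1)).sum())
        n1 = int((at_risk & (z == 1)).sum())
        n0 = int(at_risk.sum()) - n1
        ll += d1 * beta
        for l in range(d):
            ll -= np.log((n0 - l / d * (d - d1)) + (n1 - l / d * d1) * r)
    return ll


def efron_grid_argmax(times, events, z, lo=-5.0, hi=5.0, tol=1e-6):
    """Golden-section-free grid refinement of the Efron likelihood maximiser."""
    for _ in range(6):
        grid = np.linspace(lo, hi, 201)
        ll = [efron_loglik(b, times, events, z) for b in grid]
        i = int(np.argmax(ll))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def mw_auc(case_markers, control_markers):
    """Mann-Whitney AUC with half credit for ties, by direct counting."""
    wins = 0.0
    for c in case_markers:
        for k in control_markers:
            if c > k:
                wins += 1.0
            elif c == k:
                wins += 0.5
    return wins / (len(case_markers) * len(control_markers))


def welch_oracle(x, y):
    """Textbook Welch statistic and Welch-Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = x.var(ddof=1) / len(x)
    vy = y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    return t, df


def paired_oracle(x, y):
    """One-sample t on the paired differences."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
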