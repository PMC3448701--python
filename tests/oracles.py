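"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (explicit loops, exhaustive scans,
scalar optimization) and shares no code with the package internals.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm


def cox_loglik_naive(beta: float, x, time, event) -> float:
    """Efron partial log-likelihood by direct risk-set loops."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for tau in np.unique(time[event == 1]):
        D = np.flatnonzero((time == tau) & (event == 1))
        R = np.flatnonzero(time >= tau)
        d = len(D)
        s0 = sum(np.exp(beta * x[i]) for i in D)
        S0 = sum(np.exp(beta * x[i]) for i in R)
        ll += sum(beta * x[i] for i in D)
        for el in range(d):
            ll -= np.log(S0 - (el / d) * s0)
    return ll


def cox_oracle(x, time, event):
    """Maximize the naive partial likelihood by bounded scalar search.

    Returns (beta, se, wald_p); se from a numerical second derivative.
    """
    neg = lambda b: -cox_loglik_naive(b, x, time, event)
    res = minimize_scalar(neg, bounds=(-50, 50), method="bounded",
                          options={"xatol": 1e-12})
    beta = float(res.x)
    h = 1e-5
    info = -(
        cox_loglik_naive(beta + h, x, time, event)
        - 2.0 * cox_loglik_naive(beta, x, time, event)
        + cox_loglik_naive(beta - h, x, time, event)
    ) / h**2
    se = 1.0 / np.sqrt(info)
    p = 2.0 * norm.sf(abs(beta) / se)
    return beta, float(se), float(p)


def upgma_naive(d: np.ndarray):
    """O(n^3) average-linkage agglomeration.

    Returns a list of merges (id_a, id_b, height, size) with leaves 0..n-1
    and new clusters numbered n, n+1, ...; candidate pairs are scanned in
    lowest-index order so exact ties break toward the earliest pair.
    """
    d = np.asarray(d, float)
    n = d.shape[0]
    members = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(members) > 1:
        ids = sorted(members)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                dist = np.mean(
                    [d[i, j] for i in members[a] for j in members[b]]
                )
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, a, b)
        dist, a, b = best
        members[next_id] = members.pop(a) + members.pop(b)
        merges.append((a, b, dist, len(members[next_id])))
        next_id += 1
    return merges


def best_1d_split(x: np.ndarray):
    """Exhaustive optimal two-group split of 1-D data by within-group SS.

    Returns a boolean mask marking the higher-mean group.
    """
    x = np.asarray(x, float)
    xs = np.sort(x)
    n = len(xs)
    best = (np.inf, None)
    for k in range(1, n):
        left, right = xs[:k], xs[k:]
        ss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if ss < best[0]:
            best = (ss, (xs[k - 1] + xs[k]) / 2.0)
    return x > best[1]


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums the probability of every table (same margins) whose probability
    does not exceed the observed one, using the R-style relative gate.
    """
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    denom = comb(n, r1)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    probs = {
        k: comb(c1, k) * comb(n - c1, r1 - k) / denom for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


def km_naive(time, event):
    """Product-limit survival estimate at each distinct event time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    out = [(0.0, 1.0)]
    for tau in np.unique(time[event == 1]):
        at_risk = int((time >= tau).sum())
        deaths = int(((time == tau) & (event == 1)).sum())
        s *= 1.0 - deaths / at_risk
        out.append((float(tau), s))
    return out
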