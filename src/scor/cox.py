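"""Univariate Cox proportional-hazards fits, vectorized across genes.

The screening stage refits thousands of single-covariate Cox models per
resampling round, so the solver is written to fit every gene simultaneously:
one Newton-Raphson iteration updates the whole vector of per-gene
coefficients using shared risk-set structure. Ties are handled with the
Efron approximation (the ``coxph`` default in the R survival package), and
the reported p value is the two-sided Wald test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import SurvivalData

__all__ = ["CoxFitResult", "InsufficientEventsError", "fit_univariate_cox", "fit_cox_batch"]

_MAX_ITER = 40
_TOL = 1e-9


class InsufficientEventsError(ValueError):
    """Raised when a cohort (or subset) has too few observed events to fit."""


@dataclass
class CoxFitResult:
    """Result of one univariate Cox fit.

    ``coefficient`` is the log hazard ratio per expression unit;
    ``direction`` is "poor" for a positive coefficient (higher expression,
    higher hazard) and "good" otherwise.
    """

    coefficient: float
    standard_error: float
    p_value: float
    converged: bool

    @property
    def direction(self) -> str:
        return "poor" if self.coefficient > 0 else "good"


class _RiskSetStructure:
    """Precomputed sort order, risk-set boundaries and tie groups."""

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if event.sum() < 2:
            raise InsufficientEventsError(
                f"need at least 2 observed events, got {int(event.sum())}"
            )
        order = np.argsort(time, kind="stable")
        self.order = order
        t = time[order]
        e = event[order]
        ev_times = np.unique(t[e == 1])
        # risk set at event time tau = samples with t >= tau: suffix starting
        # at the first sorted position holding tau
        self.starts = np.searchsorted(t, ev_times, side="left")
        ev_idx = []
        group_starts = []
        term_group = []
        term_frac = []
        for k, tau in enumerate(ev_times):
            members = np.flatnonzero((t == tau) & (e == 1))
            group_starts.append(len(ev_idx))
            ev_idx.extend(members.tolist())
            d = len(members)
            for l in range(d):
                term_group.append(k)
                term_frac.append(l / d)
        self.ev_idx = np.array(ev_idx, dtype=int)
        self.group_starts = np.array(group_starts, dtype=int)
        self.term_group = np.array(term_group, dtype=int)
        self.term_frac = np.array(term_frac, dtype=float)
        self.n = len(t)


def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[:, ::-1], axis=1)[:, ::-1]


def _efron(beta: np.ndarray, xs: np.ndarray, rs: _RiskSetStructure):
    """Log partial likelihood, gradient and information for each gene."""
    z = beta[:, None] * xs
    z = np.clip(z, -700, 700)  # guard exp overflow for diverging fits
    w = np.exp(z)
    wx = w * xs
    wx2 = wx * xs
    S0 = _revcumsum(w)[:, rs.starts]
    S1 = _revcumsum(wx)[:, rs.starts]
    S2 = _revcumsum(wx2)[:, rs.starts]
    s0 = np.add.reduceat(w[:, rs.ev_idx], rs.group_starts, axis=1)
    s1 = np.add.reduceat(wx[:, rs.ev_idx], rs.group_starts, axis=1)
    s2 = np.add.reduceat(wx2[:, rs.ev_idx], rs.group_starts, axis=1)
    tg, fr = rs.term_group, rs.term_frac
    D = S0[:, tg] - fr * s0[:, tg]
    N1 = S1[:, tg] - fr * s1[:, tg]
    N2 = S2[:, tg] - fr * s2[:, tg]
    sum_x_events = xs[:, rs.ev_idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = beta * sum_x_events - np.log(D).sum(axis=1)
        r1 = N1 / D
        grad = sum_x_events - r1.sum(axis=1)
        info = (N2 / D - r1**2).sum(axis=1)
    return ll, grad, info


def fit_cox_batch(X: np.ndarray, surv: SurvivalData) -> dict[str, np.ndarray]:
    """Fit a univariate Cox model per row of ``X`` against shared survival.

    Parameters
    ----------
    X : ndarray of shape (n_genes, n_samples)
        One covariate per row, columns in the order of ``surv.sample_ids``.
    surv : SurvivalData

    Returns
    -------
    dict with arrays ``coefficient``, ``standard_error``, ``p_value`` and
    boolean ``converged``, one entry per row. Constant rows are flagged
    non-converged with p = 1 (degenerate covariate) rather than raising, so
    a screening pass over many genes never aborts mid-batch.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != surv.n_samples:
        raise ValueError("covariate columns must match survival samples")
    rs = _RiskSetStructure(surv.time, surv.event)
    xs = X[:, rs.order]
    G = xs.shape[0]
    # center each covariate: the MLE is translation invariant and the
    # centered exponentials are far better conditioned
    xs = xs - xs.mean(axis=1, keepdims=True)
    sd = xs.std(axis=1)
    degenerate = sd == 0

    beta = np.zeros(G)
    converged = np.zeros(G, dtype=bool)
    ll, grad, info = _efron(beta, xs, rs)
    active = ~degenerate
    for _ in range(_MAX_ITER):
        if not active.any():
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 0, grad / np.maximum(info, 1e-300), 0.0)
        step = np.where(active, step, 0.0)
        # step-halving: never accept an update that lowers the likelihood
        for _half in range(12):
            ll_new, grad_new, info_new = _efron(beta + step, xs, rs)
            bad = active & (~np.isfinite(ll_new) | (ll_new < ll - 1e-10))
            if not bad.any():
                break
            step[bad] *= 0.5
        newly = active & (np.abs(step) <= _TOL * (1 + np.abs(beta)))
        beta = beta + step
        ll = np.where(active, ll_new, ll)
        grad = np.where(active, grad_new, grad)
        info = np.where(active, info_new, info)
        converged |= newly
        active &= ~newly
        # runaway coefficients signal monotone likelihood; give up on them
        runaway = active & (np.abs(beta) * np.maximum(sd, 1e-12) > 100)
        active &= ~runaway

    converged &= np.isfinite(beta) & (info > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.inf)
        zstat = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(zstat))
    p = np.where(converged, p, 1.0)
    beta = np.where(degenerate, 0.0, beta)
    se = np.where(degenerate, np.inf, se)
    return {
        "coefficient": beta,
        "standard_error": se,
        "p_value": p,
        "converged": converged,
    }


def fit_univariate_cox(x, surv: SurvivalData) -> CoxFitResult:
    """Fit a single-gene Cox model; see :func:`fit_cox_batch` for conventions.

    Raises
    ------
    InsufficientEventsError
        If fewer than 2 events were observed.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a 1-D per-sample covariate")
    res = fit_cox_batch(x[None, :], surv)
    return CoxFitResult(
        coefficient=float(res["coefficient"][0]),
        standard_error=float(res["standard_error"][0]),
        p_value=float(res["p_value"][0]),
        converged=bool(res["converged"][0]),
    )
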