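"""Newton solver for the stratified Cox partial likelihood.

Supports left truncation (delayed entry, for the attained-age time scale),
the Efron approximation for tied event times, and stratum-specific baseline
hazards.  Risk-set sums use the suffix-cumsum identity: because entry <=
exit for every subject,

    sum_{entry < t <= exit} f  =  sum_{exit >= t} f  -  sum_{entry >= t} f,

so S0/S1/S2 at every event time come from two sorted cumulative sums rather
than an O(n^2) scan.  The design is small-p (a handful of covariates), which
keeps the per-iteration cost at O(n p^2) per stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class CoxConvergenceError(RuntimeError):
    pass


@dataclass
class StratumData:
    entry: np.ndarray   # entry age/time (0 when no delayed entry)
    time: np.ndarray    # exit time
    event: np.ndarray   # bool
    x: np.ndarray       # n x p


def _suffix_sums_at(times_sorted: np.ndarray, values_cum: np.ndarray, t: np.ndarray):
    """sum of values over indices with times_sorted >= t, per t (vectorized)."""
    idx = np.searchsorted(times_sorted, t, side="left")
    # values_cum[i] = sum of values[i:], with values_cum[n] = 0
    return values_cum[idx]


def _risk_sums(d: StratumData, w: np.ndarray, tau: np.ndarray):
    """S0, S1, S2 over the risk sets {entry < tau <= exit} at each tau."""
    n, p = d.x.shape
    wx = w[:, None] * d.x
    wxx = wx[:, :, None] * d.x[:, None, :]  # n x p x p

    def _cum(order_times, arr):
        o = np.argsort(order_times, kind="stable")
        ts = order_times[o]
        a = arr[o]
        cum = np.concatenate([np.cumsum(a[::-1], axis=0)[::-1], np.zeros((1,) + a.shape[1:])])
        return ts, cum

    t_exit, cw_exit = _cum(d.time, w[:, None])
    _, cwx_exit = _cum(d.time, wx)
    _, cwxx_exit = _cum(d.time, wxx.reshape(n, -1))
    t_ent, cw_ent = _cum(d.entry, w[:, None])
    _, cwx_ent = _cum(d.entry, wx)
    _, cwxx_ent = _cum(d.entry, wxx.reshape(n, -1))

    s0 = _suffix_sums_at(t_exit, cw_exit, tau)[:, 0] - _suffix_sums_at(t_ent, cw_ent, tau)[:, 0]
    s1 = _suffix_sums_at(t_exit, cwx_exit, tau) - _suffix_sums_at(t_ent, cwx_ent, tau)
    s2 = (
        _suffix_sums_at(t_exit, cwxx_exit, tau) - _suffix_sums_at(t_ent, cwxx_ent, tau)
    ).reshape(len(tau), p, p)
    return s0, s1, s2


def _efron_terms(s0, s1, s2, dsz, wd, wxd, wxxd, etad, p):
    """Sum Efron contributions across tie groups; vectorized over groups for
    each within-group rank l."""
    K = len(s0)
    ll = float(etad.sum())
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    max_d = int(dsz.max())
    for l in range(max_d):
        act = dsz > l
        frac = (l / dsz[act])[:, None]
        s0l = s0[act] - frac[:, 0] * wd[act]
        s1l = s1[act] - frac * wxd[act]
        s2l = s2[act] - frac[:, :, None] * wxxd[act]
        ll -= float(np.sum(np.log(s0l)))
        g = s1l / s0l[:, None]
        grad -= g.sum(axis=0)
        hess -= (s2l / s0l[:, None, None] - g[:, :, None] * g[:, None, :]).sum(axis=0)
    # deaths' own covariate sum enters gradient once per death
    return ll, grad, hess


def _stratum_contrib(d: StratumData, beta: np.ndarray):
    p = d.x.shape[1]
    if not d.event.any():
        return 0.0, np.zeros(p), np.zeros((p, p))
    eta = d.x @ beta
    shift = eta.max()
    w = np.exp(eta - shift)

    ev = d.event
    tau, inv = np.unique(d.time[ev], return_inverse=True)
    s0, s1, s2 = _risk_sums(d, w, tau)

    K = len(tau)
    dsz = np.bincount(inv, minlength=K).astype(float)
    wd = np.zeros(K)
    np.add.at(wd, inv, w[ev])
    wxd = np.zeros((K, p))
    np.add.at(wxd, inv, w[ev, None] * d.x[ev])
    wxxd = np.zeros((K, p, p))
    np.add.at(wxxd, inv, (w[ev, None] * d.x[ev])[:, :, None] * d.x[ev][:, None, :])
    etad = np.zeros(K)
    np.add.at(etad, inv, eta[ev] - shift)

    ll, grad_rs, hess_rs = _efron_terms(s0, s1, s2, dsz, wd, wxd, wxxd, etad, p)
    grad = d.x[ev].sum(axis=0) + grad_rs
    return ll, grad, hess_rs


def fit_cox(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    entry: np.ndarray | None = None,
    strata_ids: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
):
    """Maximize the stratified Efron partial likelihood by Newton's method.

    Returns ``(beta, cov, loglik)``; ``cov`` is the inverse observed
    information.  Raises :class:`CoxConvergenceError` when Newton fails to
    improve the likelihood or the information matrix is singular.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    entry = np.zeros(n) if entry is None else np.asarray(entry, dtype=float)
    if np.any(entry > time):
        raise ValueError("entry must precede exit for every subject")
    if strata_ids is None:
        strata_ids = np.zeros(n, dtype=int)

    strata: list[StratumData] = []
    for sid in pd.unique(strata_ids):
        m = strata_ids == sid
        if not event[m].any():
            continue
        strata.append(StratumData(entry=entry[m], time=time[m], event=event[m], x=x[m]))
    if not strata:
        raise ValueError("no stratum contains an event")

    def objective(beta):
        ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
        for d in strata:
            l, g, h = _stratum_contrib(d, beta)
            ll += l
            grad += g
            hess += h
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = objective(beta)
    if p == 0:  # null model: likelihood only, nothing to optimize
        return beta, np.zeros((0, 0)), float(ll)
    for _ in range(max_iter):
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            # rank-deficient design (collinear covariates in sparse strata):
            # move along the identified directions only
            step = np.linalg.pinv(info) @ grad
        # step-halving line search
        for _ in range(30):
            cand = beta + step
            ll_new, grad_new, hess_new = objective(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        else:
            raise CoxConvergenceError("step-halving failed to improve likelihood")
        delta = ll_new - ll
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if abs(delta) < tol:
            break
    else:
        raise CoxConvergenceError("Newton iteration did not converge")

    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-hess)
    return beta, cov, float(ll)


def schoenfeld_trend_test(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    beta: np.ndarray,
    entry: np.ndarray | None = None,
    strata_ids: np.ndarray | None = None,
    column: int = 0,
) -> float:
    """Grambsch-Therneau-style trend test p-value for one covariate.

    Correlates the covariate's Schoenfeld residuals with the rank of event
    time; a small p suggests a time-varying effect (non-proportionality).
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    n = len(x)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    entry = np.zeros(n) if entry is None else np.asarray(entry, dtype=float)
    if strata_ids is None:
        strata_ids = np.zeros(n, dtype=int)

    resid, times = [], []
    for sid in pd.unique(strata_ids):
        m = strata_ids == sid
        if not event[m].any():
            continue
        d = StratumData(entry=entry[m], time=time[m], event=event[m], x=x[m])
        eta = d.x @ beta
        w = np.exp(eta - eta.max())
        tau, inv = np.unique(d.time[d.event], return_inverse=True)
        s0, s1, _ = _risk_sums(d, w, tau)
        xbar = s1[:, column] / s0
        r = d.x[d.event, column] - xbar[inv]
        resid.extend(r.tolist())
        times.extend(d.time[d.event].tolist())
    if len(resid) < 3:
        raise ValueError("too few events for a trend test")
    g = stats.rankdata(times)
    rho, p = stats.pearsonr(g, resid)
    return float(p)
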