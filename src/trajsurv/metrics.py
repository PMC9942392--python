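"""Time-dependent discrimination, calibration and reclassification metrics.

All metrics operate on the landmark risk set (patients still at risk at
time s) and a prediction horizon t > s.  Discrimination is the
cumulative/dynamic AUC with inverse-probability-of-censoring weights
(IPCW) from the Kaplan–Meier estimate of the censoring distribution on the
risk set; calibration is the IPCW Brier score.  The net reclassification
improvement (NRI) and integrated discrimination improvement (IDI) compare
two risk vectors among patients whose status at t is known (events in
(s, t]; non-events observed beyond t); patients censored inside (s, t] have
unknown status and are excluded from those two indices.  Confidence
intervals are percentile bootstrap over patients with a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def risk_at(conditional_survival) -> np.ndarray:
    """Predicted event risk by the horizon: 1 - conditional survival."""
    pi = np.asarray(conditional_survival, dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("conditional survival probabilities must lie in [0, 1]")
    return 1.0 - pi


def censoring_survival(time, event):
    """Kaplan–Meier estimate of the censoring survivor function G(u) = P(C > u).

    Censorings are the 'events'; at tied times deaths are handled before
    censorings (the standard convention, so G is left-continuous at event
    times in the IPCW weights below).  Returns (times, values) of the step
    function.
    """
    time = np.asarray(time, dtype=float)
    cens = 1 - np.asarray(event).astype(int)
    order = np.argsort(time, kind="stable")
    t = time[order]
    c = cens[order]
    uniq = np.unique(t)
    n = len(t)
    G = []
    g = 1.0
    at_risk = n
    for u in uniq:
        here = t == u
        d_cens = int(c[here].sum())
        n_here = int(here.sum())
        # deaths at u leave the risk set before censorings at u
        denom = at_risk - (n_here - d_cens)
        if denom > 0 and d_cens > 0:
            g *= 1.0 - d_cens / denom
        at_risk -= n_here
        G.append(g)
    return uniq, np.asarray(G)


def _G_at(Gt, Gv, u, before=False):
    """Evaluate the censoring KM at u (or just before u)."""
    u = np.asarray(u, dtype=float)
    if before:
        idx = np.searchsorted(Gt, u, side="left") - 1
    else:
        idx = np.searchsorted(Gt, u, side="right") - 1
    out = np.ones(u.shape)
    pos = idx >= 0
    out[pos] = Gv[idx[pos]]
    return out


def _risk_set(time, s):
    time = np.asarray(time, dtype=float)
    return time > s


def td_auc(risk, time, event, s, t):
    """IPCW cumulative/dynamic AUC for the horizon t, conditional on s.

    Cases are events in (s, t]; controls are patients still at risk beyond
    t.  Case weight 1/G(T_i^-), control weight 1/G(t), G estimated on the
    risk set.  Ties in risk count 1/2.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    rs = _risk_set(time, s)
    risk, time, event = risk[rs], time[rs], event[rs]
    cases = (time <= t) & (event == 1)
    controls = time > t
    if not cases.any() or not controls.any():
        raise ValueError(f"no comparable case/control pairs in ({s}, {t}]")
    Gt, Gv = censoring_survival(time, event)
    w_case = 1.0 / _G_at(Gt, Gv, time[cases], before=True)
    w_ctrl = np.full(int(controls.sum()), 1.0 / _G_at(Gt, Gv,
                                                      np.array([t]))[0])
    rc = risk[cases][:, None]
    rk = risk[controls][None, :]
    win = (rc > rk) + 0.5 * (rc == rk)
    W = w_case[:, None] * w_ctrl[None, :]
    return float((win * W).sum() / W.sum())


def brier(risk, time, event, s, t):
    """IPCW Brier score at horizon t for conditional-on-s predictions."""
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    rs = _risk_set(time, s)
    risk, time, event = risk[rs], time[rs], event[rs]
    surv_pred = 1.0 - risk
    Gt, Gv = censoring_survival(time, event)
    died = (time <= t) & (event == 1)
    alive = time > t
    g_died = _G_at(Gt, Gv, time[died], before=True)
    g_t = _G_at(Gt, Gv, np.array([t]))[0]
    if (died.any() and np.any(g_died <= 0)) or (alive.any() and g_t <= 0):
        raise ValueError("censoring distribution reaches zero before the "
                         "horizon; Brier score undefined")
    n = len(time)
    contrib = np.zeros(n)
    contrib[died] = (0.0 - surv_pred[died]) ** 2 / g_died
    contrib[alive] = (1.0 - surv_pred[alive]) ** 2 / g_t
    return float(contrib.sum() / n)


@dataclass
class ReclassificationResult:
    """NRI or IDI estimate with its bootstrap confidence interval."""

    estimate: float
    ci_lower: float
    ci_upper: float
    detail: dict

    def __iter__(self):
        yield from (self.estimate, self.ci_lower, self.ci_upper)


def _known_status(time, event, s, t):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    rs = _risk_set(time, s)
    events = rs & (time <= t) & (event == 1)
    nonevents = rs & (time > t)
    return events, nonevents


def _nri_point(risk_new, risk_old, events, nonevents):
    up = risk_new > risk_old
    down = risk_new < risk_old
    n_e = int(events.sum())
    n_ne = int(nonevents.sum())
    if n_e == 0 or n_ne == 0:
        raise ValueError("NRI undefined: need both events and non-events "
                         "with known status")
    up_e = up[events].sum() / n_e
    down_e = down[events].sum() / n_e
    up_ne = up[nonevents].sum() / n_ne
    down_ne = down[nonevents].sum() / n_ne
    nri = (up_e - down_e) + (down_ne - up_ne)
    return nri, up_e, down_e, up_ne, down_ne


def nri(risk_new, risk_old, time, event, s, t, n_boot: int = 1000,
        seed: int = 0) -> ReclassificationResult:
    """Category-free net reclassification improvement, in percent.

    Events in (s, t] vs non-events beyond t; exact ties in risks count
    toward neither direction.  Percentile bootstrap CI over patients.
    """
    risk_new = np.asarray(risk_new, dtype=float)
    risk_old = np.asarray(risk_old, dtype=float)
    events, nonevents = _known_status(time, event, s, t)
    point, up_e, down_e, up_ne, down_ne = _nri_point(risk_new, risk_old,
                                                     events, nonevents)
    lo, hi = _bootstrap_ci(
        lambda idx: _nri_point(risk_new[idx], risk_old[idx], events[idx],
                               nonevents[idx])[0],
        len(risk_new), n_boot, seed)
    return ReclassificationResult(
        estimate=100.0 * point, ci_lower=100.0 * lo, ci_upper=100.0 * hi,
        detail={"events_up_pct": 100.0 * up_e,
                "events_down_pct": 100.0 * down_e,
                "nonevents_up_pct": 100.0 * up_ne,
                "nonevents_down_pct": 100.0 * down_ne,
                "n_events": int(events.sum()),
                "n_nonevents": int(nonevents.sum())})


def _idi_point(risk_new, risk_old, events, nonevents):
    if not events.any() or not nonevents.any():
        raise ValueError("IDI undefined: need both events and non-events "
                         "with known status")
    d_e = risk_new[events].mean() - risk_old[events].mean()
    d_ne = risk_new[nonevents].mean() - risk_old[nonevents].mean()
    return d_e - d_ne


def idi(risk_new, risk_old, time, event, s, t, n_boot: int = 1000,
        seed: int = 0) -> ReclassificationResult:
    """Integrated discrimination improvement with bootstrap CI."""
    risk_new = np.asarray(risk_new, dtype=float)
    risk_old = np.asarray(risk_old, dtype=float)
    events, nonevents = _known_status(time, event, s, t)
    point = _idi_point(risk_new, risk_old, events, nonevents)
    lo, hi = _bootstrap_ci(
        lambda idx: _idi_point(risk_new[idx], risk_old[idx], events[idx],
                               nonevents[idx]),
        len(risk_new), n_boot, seed)
    return ReclassificationResult(
        estimate=float(point), ci_lower=lo, ci_upper=hi,
        detail={"events_mean_new": float(risk_new[events].mean()),
                "events_mean_old": float(risk_old[events].mean()),
                "nonevents_mean_new": float(risk_new[nonevents].mean()),
                "nonevents_mean_old": float(risk_old[nonevents].mean()),
                "n_events": int(events.sum()),
                "n_nonevents": int(nonevents.sum())})


def _bootstrap_ci(stat, n, n_boot, seed, alpha=0.05):
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            vals.append(stat(idx))
        except ValueError:
            continue
    if not vals:
        return float("nan"), float("nan")
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
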