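"""Metric kernels against brute-force oracles and closed forms.

The oracles here are deliberately naive re-implementations: explicit
double loops over patient pairs with a hand-rolled Kaplan–Meier for the
censoring distribution.  The production kernels must match them to 1e-12
on small hand-set cohorts.
"""

import numpy as np
import pytest

from trajsurv.metrics import (
    brier,
    censoring_survival,
    idi,
    nri,
    risk_at,
    td_auc,
)

S, T = 12.0, 36.0


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def km_censoring_oracle(time, event):
    """Product-limit estimate of P(C > u), censorings as events."""
    def G(u):
        g = 1.0
        for v in sorted(set(time)):
            if v > u:
                break
            n_at_risk = sum(1 for ti in time if ti >= v)
            deaths_here = sum(1 for ti, ei in zip(time, event)
                              if ti == v and ei == 1)
            cens_here = sum(1 for ti, ei in zip(time, event)
                            if ti == v and ei == 0)
            denom = n_at_risk - deaths_here
            if cens_here and denom > 0:
                g *= 1 - cens_here / denom
        return g
    return G


def auc_oracle(risk, time, event, s, t):
    keep = [i for i in range(len(time)) if time[i] > s]
    risk = [risk[i] for i in keep]
    time = [time[i] for i in keep]
    event = [event[i] for i in keep]
    G = km_censoring_oracle(time, event)
    cases = [i for i in range(len(time)) if time[i] <= t and event[i] == 1]
    ctrls = [i for i in range(len(time)) if time[i] > t]
    num = den = 0.0
    for i in cases:
        wi = 1.0 / G(time[i] - 1e-9)
        for j in ctrls:
            wj = 1.0 / G(t)
            if risk[i] > risk[j]:
                num += wi * wj
            elif risk[i] == risk[j]:
                num += 0.5 * wi * wj
            den += wi * wj
    return num / den


def brier_oracle(risk, time, event, s, t):
    keep = [i for i in range(len(time)) if time[i] > s]
    risk = [risk[i] for i in keep]
    time = [time[i] for i in keep]
    event = [event[i] for i in keep]
    G = km_censoring_oracle(time, event)
    total = 0.0
    for i in range(len(time)):
        surv = 1 - risk[i]
        if time[i] <= t and event[i] == 1:
            total += (0 - surv) ** 2 / G(time[i] - 1e-9)
        elif time[i] > t:
            total += (1 - surv) ** 2 / G(t)
    return total / len(time)


def nri_oracle(rn, ro, time, event, s, t):
    ev = [i for i in range(len(time))
          if s < time[i] <= t and event[i] == 1]
    ne = [i for i in range(len(time)) if time[i] > t]
    up_e = sum(rn[i] > ro[i] for i in ev) / len(ev)
    dn_e = sum(rn[i] < ro[i] for i in ev) / len(ev)
    up_n = sum(rn[i] > ro[i] for i in ne) / len(ne)
    dn_n = sum(rn[i] < ro[i] for i in ne) / len(ne)
    return 100 * ((up_e - dn_e) + (dn_n - up_n))


def idi_oracle(rn, ro, time, event, s, t):
    ev = [i for i in range(len(time))
          if s < time[i] <= t and event[i] == 1]
    ne = [i for i in range(len(time)) if time[i] > t]
    d_e = sum(rn[i] for i in ev) / len(ev) - sum(ro[i] for i in ev) / len(ev)
    d_n = sum(rn[i] for i in ne) / len(ne) - sum(ro[i] for i in ne) / len(ne)
    return d_e - d_n


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def test_risk_is_one_minus_conditional_survival():
    assert risk_at(1.0) == 0.0
    assert risk_at(np.array([0.8]))[0] == pytest.approx(0.2)
    pi = np.array([0.9, 0.8, 0.55])       # non-increasing survival over t
    assert np.all(np.diff(risk_at(pi)) > 0)
    with pytest.raises(ValueError):
        risk_at([1.2])


def test_censoring_km_matches_oracle(hand_cohort):
    time = hand_cohort["time_months"].to_numpy()
    event = hand_cohort["event"].to_numpy()
    Gt, Gv = censoring_survival(time, event)
    G = km_censoring_oracle(list(time), list(event))
    for u, g in zip(Gt, Gv):
        assert g == pytest.approx(G(u), abs=1e-12)


def test_td_auc_equals_pairwise_oracle(hand_cohort):
    r = hand_cohort["risk"].to_numpy()
    time = hand_cohort["time_months"].to_numpy()
    event = hand_cohort["event"].to_numpy()
    got = td_auc(r, time, event, S, T)
    want = auc_oracle(list(r), list(time), list(event), S, T)
    assert got == pytest.approx(want, abs=1e-12)


def test_td_auc_perfect_separation():
    time = np.array([20, 25, 30, 50, 60, 70.0])
    event = np.array([1, 1, 1, 0, 0, 0])
    risk = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
    # treat everyone as observed beyond t: controls administratively known
    event_ctrl = np.array([1, 1, 1, 1, 1, 1])
    assert td_auc(risk, time, event_ctrl, S, T) == pytest.approx(1.0)


def test_td_auc_null_risks_near_half():
    rng = np.random.default_rng(42)
    n = 2000
    time = rng.uniform(13, 100, n)
    event = np.ones(n, dtype=int)          # no censoring
    risk = rng.uniform(size=n)
    auc = td_auc(risk, time, event, S, T)
    n1 = int(((time <= T)).sum())
    n0 = n - n1
    se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
    assert abs(auc - 0.5) < 3 * se


def test_td_auc_requires_cases_and_controls():
    with pytest.raises(ValueError):
        td_auc([0.5, 0.4], [100, 90], [0, 0], S, T)


def test_td_auc_matches_sksurv_when_uncensored():
    """Independent cross-check: with no censoring the IPCW weights are all
    one, so our estimator must agree with scikit-survival's."""
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    rng = np.random.default_rng(3)
    n = 150
    time = rng.uniform(13, 90, n)
    event = np.ones(n, dtype=bool)
    risk = rng.uniform(size=n)
    y = Surv.from_arrays(event, time)
    want = cumulative_dynamic_auc(y, y, risk, [T])[0][0]
    got = td_auc(risk, time, event.astype(int), 0.0, T)
    assert got == pytest.approx(want, abs=1e-10)


def test_auc_invariant_under_monotone_transform_brier_not(hand_cohort):
    r = hand_cohort["risk"].to_numpy()
    time = hand_cohort["time_months"].to_numpy()
    event = hand_cohort["event"].to_numpy()
    r2 = np.sqrt(r)                         # strictly monotone
    assert td_auc(r, time, event, S, T) == pytest.approx(
        td_auc(r2, time, event, S, T), abs=1e-12)
    assert brier(r, time, event, S, T) != pytest.approx(
        brier(r2, time, event, S, T), abs=1e-6)


def test_brier_equals_direct_sum_oracle(hand_cohort):
    r = hand_cohort["risk"].to_numpy()
    time = hand_cohort["time_months"].to_numpy()
    event = hand_cohort["event"].to_numpy()
    got = brier(r, time, event, S, T)
    want = brier_oracle(list(r), list(time), list(event), S, T)
    assert got == pytest.approx(want, abs=1e-12)


def test_brier_perfect_predictions_zero():
    time = np.array([20, 30, 50, 60.0])
    event = np.array([1, 1, 1, 1])
    risk = np.array([1.0, 1.0, 0.0, 0.0])
    assert brier(risk, time, event, S, T) == pytest.approx(0.0, abs=1e-15)


def test_brier_constant_risk_closed_form():
    # uncensored binary outcome with event fraction q, constant risk p
    n_e, n_ne, p = 3, 7, 0.3
    time = np.array([20.0] * n_e + [80.0] * n_ne)
    event = np.ones(n_e + n_ne, dtype=int)
    risk = np.full(n_e + n_ne, p)
    q = n_e / (n_e + n_ne)
    want = q * (1 - p) ** 2 + (1 - q) * p ** 2
    assert brier(risk, time, event, S, T) == pytest.approx(want, abs=1e-15)


def test_nri_equals_enumeration_oracle():
    time = np.array([15, 20, 30, 40, 50, 70.0])
    event = np.array([1, 1, 1, 0, 1, 0])
    rn = np.array([0.8, 0.3, 0.6, 0.2, 0.5, 0.4])
    ro = np.array([0.5, 0.5, 0.6, 0.4, 0.3, 0.2])
    got = nri(rn, ro, time, event, S, T, n_boot=10, seed=0)
    want = nri_oracle(rn, ro, time, event, S, T)
    assert got.estimate == pytest.approx(want, abs=1e-12)


def test_idi_equals_enumeration_oracle():
    time = np.array([15, 20, 30, 40, 50, 70.0])
    event = np.array([1, 1, 1, 0, 1, 0])
    rn = np.array([0.8, 0.3, 0.6, 0.2, 0.5, 0.4])
    ro = np.array([0.5, 0.5, 0.6, 0.4, 0.3, 0.2])
    got = idi(rn, ro, time, event, S, T, n_boot=10, seed=0)
    want = idi_oracle(rn, ro, time, event, S, T)
    assert got.estimate == pytest.approx(want, abs=1e-12)


def test_identical_risks_give_zero_nri_and_idi():
    time = np.array([15, 20, 40, 70.0])
    event = np.array([1, 1, 0, 0])
    r = np.array([0.4, 0.6, 0.2, 0.3])
    res = nri(r, r.copy(), time, event, S, T, n_boot=10, seed=0)
    assert res.estimate == 0.0
    assert res.detail["events_up_pct"] == 0.0
    assert res.detail["events_down_pct"] == 0.0
    assert idi(r, r.copy(), time, event, S, T, n_boot=10,
               seed=0).estimate == 0.0


def test_nri_idi_antisymmetric_under_model_swap():
    time = np.array([15, 20, 30, 40, 50, 70.0])
    event = np.array([1, 1, 1, 0, 1, 0])
    rn = np.array([0.8, 0.3, 0.6, 0.2, 0.5, 0.4])
    ro = np.array([0.5, 0.5, 0.6, 0.4, 0.3, 0.2])
    assert nri(rn, ro, time, event, S, T, n_boot=10).estimate == \
        pytest.approx(-nri(ro, rn, time, event, S, T, n_boot=10).estimate,
                      abs=1e-12)
    assert idi(rn, ro, time, event, S, T, n_boot=10).estimate == \
        pytest.approx(-idi(ro, rn, time, event, S, T, n_boot=10).estimate,
                      abs=1e-12)


def test_idi_perfect_vs_useless_is_one():
    time = np.array([20, 25, 60, 70.0])
    event = np.array([1, 1, 1, 1])
    perfect = np.array([1.0, 1.0, 0.0, 0.0])
    useless = np.full(4, 0.5)
    assert idi(perfect, useless, time, event, S, T,
               n_boot=10).estimate == pytest.approx(1.0)


def test_nri_requires_both_groups():
    with pytest.raises(ValueError):
        nri([0.4, 0.5], [0.3, 0.6], [20, 30], [1, 1], S, T, n_boot=5)


def test_censored_in_window_excluded_from_reclassification():
    """A patient censored inside (s, t] has unknown status and must not
    contribute to either NRI group."""
    time = np.array([20, 20, 25, 70.0])
    event = np.array([1, 0, 1, 0])          # second patient censored at 20
    rn = np.array([0.9, 0.9, 0.8, 0.1])
    ro = np.array([0.1, 0.1, 0.2, 0.9])
    res = nri(rn, ro, time, event, S, T, n_boot=10)
    assert res.detail["n_events"] == 2
    assert res.detail["n_nonevents"] == 1
    assert res.estimate == pytest.approx(100 * (1.0 + 1.0), abs=1e-12)
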