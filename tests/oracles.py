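"""Independent brute-force re-implementations used as test oracles.

Everything here is deliberately naive — plain loops and counting, no numpy
vectorization, no reuse of the package's query functions — so agreement with
the package is a genuine dual-route check of the decision rules, not a
tautology.
"""

from __future__ import annotations

import math

NOT_REPORTED = "oracle_not_reported"
NOT_REACHED = "oracle_not_reached"


def naive_km(times, events):
    """Product-limit by direct counting over the distinct observed times.

    Returns (grid, surv, at_risk) as plain lists; every distinct observed
    time is listed, censoring-only times as flat steps.
    """
    pairs = sorted(zip(times, events))
    grid, surv, at_risk = [], [], []
    s = 1.0
    n = len(pairs)
    for t in sorted({t for t, _ in pairs}):
        risk = sum(1 for u, _ in pairs if u >= t)
        deaths = sum(1 for u, e in pairs if u == t and e)
        s *= (risk - deaths) / risk
        grid.append(t)
        surv.append(s)
        at_risk.append(risk)
    return grid, surv, at_risk


def empirical_survival(times, t):
    """P(T > t) by counting, for samples with no censoring."""
    return sum(1 for u in times if u > t) / len(times)


def step_lookup(grid, surv, max_followup, t):
    """Right-continuous step value by linear scan; sentinel beyond follow-up."""
    if t > max_followup + 1e-9:
        return NOT_REPORTED
    value = 1.0
    for u, s in zip(grid, surv):
        if u <= t + 1e-9:
            value = s
        else:
            break
    return value


def naive_median(grid, surv):
    for u, s in zip(grid, surv):
        if s <= 0.5 + 1e-9:
            return u
    return NOT_REACHED


def naive_rmst(grid, surv, tau):
    area = 0.0
    prev_t, prev_s = 0.0, 1.0
    for u, s in zip(grid, surv):
        if u >= tau:
            break
        area += (u - prev_t) * prev_s
        prev_t, prev_s = u, s
    area += (tau - prev_t) * prev_s
    return area


def _curve_tuple(curve):
    return (list(curve.times), list(curve.surv), list(curve.at_risk),
            curve.max_followup)


def naive_plateau(curve, window_frac=0.2, drop_tol=0.05, min_at_risk=10):
    grid, surv, at_risk, mf = _curve_tuple(curve)
    start = (1 - window_frac) * mf
    drop = (step_lookup(grid, surv, mf, start)
            - step_lookup(grid, surv, mf, mf))
    risk = None
    for u, r in zip(grid, at_risk):
        if u >= start - 1e-9:
            risk = r
            break
    if risk is None:
        risk = at_risk[-1] if at_risk else curve.n_enrolled
    return drop < drop_tol - 1e-9 and risk >= min_at_risk


def oracle_toc_met(test, control, ratio_threshold=1.5, floor_threshold=0.20):
    """Direct evaluation of the four tail-of-the-curve criteria."""
    cg, cs, _, cmf = _curve_tuple(control)
    tg, ts, _, tmf = _curve_tuple(test)
    median = naive_median(cg, cs)
    if median is NOT_REACHED:
        return False
    t2 = 2 * median
    s_ctrl = step_lookup(cg, cs, cmf, t2)
    s_test = step_lookup(tg, ts, tmf, t2)
    if s_ctrl is NOT_REPORTED or s_test is NOT_REPORTED:
        return False
    if s_ctrl < floor_threshold - 1e-9:
        return False
    if s_ctrl <= 0:
        return False
    return s_test / s_ctrl >= ratio_threshold - 1e-9


def oracle_award_toc(trial, ratio_threshold=1.5, floor_threshold=0.20,
                     os_strict=False):
    """(awarded, endpoint, points) by direct application of the award rule."""
    os_ok = trial.os_reported and not trial.os_obscured_by_crossover
    if os_ok and oracle_toc_met(trial.curve("OS", "test"),
                                trial.curve("OS", "control"),
                                ratio_threshold, floor_threshold):
        return True, "OS", 20
    pfs_allowed = trial.pfs_reported and (not os_ok or not os_strict)
    if pfs_allowed and oracle_toc_met(trial.curve("PFS", "test"),
                                      trial.curve("PFS", "control"),
                                      ratio_threshold, floor_threshold):
        return True, "PFS", 16
    return False, "none", 0


def oracle_award_ltp(trial, delta_threshold=0.10, window_frac=0.2,
                     drop_tol=0.05, min_at_risk=10, coprimary_to="OS"):
    """(awarded, adjustment) by direct application of the plateau rule."""
    if not trial.primary_significant or trial.hematological:
        return False, "none"
    endpoint = (trial.primary_endpoint if trial.primary_endpoint in ("OS", "PFS")
                else coprimary_to)
    reported = trial.os_reported if endpoint == "OS" else trial.pfs_reported
    if not reported:
        return False, "none"
    test = trial.curve(endpoint, "test")
    control = trial.curve(endpoint, "control")
    if trial.plateau_override and endpoint in trial.plateau_override:
        plateau = trial.plateau_override[endpoint]
    else:
        plateau = naive_plateau(test, window_frac, drop_tol, min_at_risk)
    if not plateau:
        return False, "none"
    cg, cs, _, cmf = _curve_tuple(control)
    tg, ts, _, tmf = _curve_tuple(test)
    median = naive_median(cg, cs)
    if endpoint == "OS":
        t_eval = 60.0 if (median is not NOT_REACHED and median <= 12 + 1e-9) else 84.0
    else:
        t_eval = 12.0 if (median is not NOT_REACHED and median <= 6 + 1e-9) else 24.0
    s_test = step_lookup(tg, ts, tmf, t_eval)
    s_ctrl = step_lookup(cg, cs, cmf, t_eval)
    if s_test is NOT_REPORTED or s_ctrl is NOT_REPORTED:
        return False, "none"
    if endpoint == "OS":
        met = s_test > s_ctrl
        kind = "os_curative_scoring"
    else:
        met = s_test - s_ctrl >= delta_threshold - 1e-9
        kind = "pfs_upgrade"
    return (True, kind) if met else (False, "none")


def cure_model_rmst(pi, lam, tau):
    """Closed-form integral of S(t) = pi + (1-pi) e^(-lam t) on [0, tau]."""
    return pi * tau + (1 - pi) * (1 - math.exp(-lam * tau)) / lam
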