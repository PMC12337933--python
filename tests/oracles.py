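"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in the most literal way possible
(day-by-day boolean arrays, exhaustive window scans, hand-rolled Newton
iterations) and shares no code with the package internals it checks.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np


def day_by_day_coverage(dispensings, policy: str, horizon: int) -> np.ndarray:
    """Boolean covered-day array by naive daily simulation."""
    covered = np.zeros(horizon, dtype=bool)
    if policy == "truncate":
        for d, s in dispensings:
            covered[max(d, 0): min(d + s, horizon)] = True
    else:  # carryover: bank every dispensed day, consume one per day
        by_day = defaultdict(int)
        for d, s in dispensings:
            by_day[d] += s
        buffer = 0
        for t in range(horizon):
            buffer += by_day.get(t, 0)
            if buffer > 0:
                covered[t] = True
                buffer -= 1
    return covered


def intervals_to_bool(intervals, horizon: int) -> np.ndarray:
    out = np.zeros(horizon, dtype=bool)
    for s, e in intervals:
        out[max(s, 0): min(e, horizon)] = True
    return out


def scan_patterns(
    same_class,
    others,
    observe_end: int,
    gap_days: int = 180,
    window: int = 180,
):
    """Exhaustive day-scan pattern classification.

    ``same_class``: (day, supply) of the initial class; ``others``: (day,
    target) of other classes / FDCs.  Returns a dict with disc/switch/addon
    events and the continuation flag.
    """
    horizon = observe_end + gap_days + window + sum(s for _, s in same_class) + 400
    covered = day_by_day_coverage(same_class, "carryover", horizon)
    same_days = sorted(d for d, _ in same_class)

    # supply-exhaustion days: first uncovered day after a covered run
    ends = [
        t
        for t in range(1, horizon)
        if covered[t - 1] and not covered[t]
    ]
    disc = None
    for e in ends:
        if e >= observe_end:
            break
        if not any(e < d <= e + gap_days for d in same_days):
            disc = e
            break

    addon = None
    for d, t in sorted(others):
        if d >= observe_end or (disc is not None and d >= disc):
            break
        if 0 <= d < horizon and covered[d]:
            addon = (d, t)
            break

    switch = None
    if disc is not None:
        for d, t in sorted(others):
            if d >= observe_end:
                break
            if disc < d <= disc + window:
                switch = (d, t)
                break

    return {
        "disc": disc,
        "switch": switch,
        "addon": addon,
        "continuation": disc is None and switch is None and addon is None,
    }


def scan_followup_end(
    study_end_day: int,
    max_days: int,
    acute_days,
    own_supply_ends,
    change_days,
):
    """First-trigger day scan for the follow-up end rule.

    ``study_end_day`` is the exclusive end implied by the study period;
    ``own_supply_ends`` the supply-end day of every index-class dispensing;
    ``acute_days`` / ``change_days`` the day offsets of censoring dispensings.
    Ties resolve in the listed priority order.
    """
    acute = sorted(d for d in acute_days if d > 0)
    change = sorted(d for d in change_days if d > 0)
    last_supply_end = max(own_supply_ends)
    t = 1
    while True:
        if t == study_end_day:
            return t, "study_end"
        if t == max_days:
            return t, "max_3780"
        if acute and t == acute[0]:
            return t, "acute_cv_drug"
        if t == last_supply_end:
            return t, "last_exposure_supply_end"
        if change and t == change[0]:
            return t, "regimen_change"
        t += 1


def newton_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Unpenalized logistic MLE by plain Newton-Raphson (intercept first)."""
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(A.shape[1])
    for _ in range(100):
        p = 1.0 / (1.0 + np.exp(-A @ beta))
        g = A.T @ (y - p)
        H = (A * (p * (1 - p))[:, None]).T @ A
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def product_limit(times, events):
    """Hand-rolled Kaplan-Meier estimate: {time: survival} at event times."""
    order = np.argsort(times)
    times = np.asarray(times, float)[order]
    events = np.asarray(events, bool)[order]
    n = len(times)
    surv = 1.0
    out = {}
    for t in np.unique(times):
        at_risk = (times >= t).sum()
        d = int(((times == t) & events).sum())
        if d:
            surv *= 1.0 - d / at_risk
        out[float(t)] = surv
    return out
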