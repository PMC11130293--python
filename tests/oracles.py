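"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results with the dumbest possible method
(pure-python tallies, an explicit optimal-transport linear program) and
must stay independent of the implementation they check.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter

import numpy as np
from scipy.optimize import linprog


def brute_force_weekly_home(events: list[tuple[dt.datetime, str]],
                            comuna_of: dict[str, str],
                            study_start: dt.date,
                            n_weeks: int) -> dict[int, str]:
    """Tally night-time weekday pings per (week, antenna) one event at a time.

    Night window 22:00-06:00, pings before 06:00 belong to the previous
    evening; evenings Monday-Friday qualify; weeks are Monday-start from the
    week containing study_start; ties go to the smallest antenna_id.
    """
    week0 = study_start - dt.timedelta(days=study_start.weekday())
    tallies: dict[int, Counter] = {}
    for ts, antenna in events:
        if ts.hour >= 22:
            evening = ts.date()
        elif ts.hour < 6:
            evening = ts.date() - dt.timedelta(days=1)
        else:
            continue
        if evening.weekday() > 4:
            continue
        week = (evening - week0).days // 7
        if not (0 <= week < n_weeks):
            continue
        tallies.setdefault(week, Counter())[antenna] += 1
    result = {}
    for week, counter in tallies.items():
        best = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        result[week] = comuna_of[best]
    return result


def lp_wasserstein(p: np.ndarray, q: np.ndarray, coords: np.ndarray) -> float:
    """Exact 1-Wasserstein distance by solving the transport linear program."""
    p = np.asarray(p, dtype=float) / np.sum(p)
    q = np.asarray(q, dtype=float) / np.sum(q)
    n = len(p)
    cost = np.abs(coords[:, None] - coords[None, :]).ravel()
    a_eq = []
    for i in range(n):  # row marginals
        row = np.zeros((n, n))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(n):  # column marginals
        col = np.zeros((n, n))
        col[:, j] = 1
        a_eq.append(col.ravel())
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.concatenate([p, q]),
                  bounds=(0, None), method="highs")
    assert res.success, res.message
    return float(res.fun)


def interval_scan_in_quarantine(intervals: list[tuple[str, dt.date, dt.date]],
                                comuna: str, day: dt.date) -> bool:
    """Membership by scanning every raw (possibly overlapping) interval."""
    return any(c == comuna and s <= day < e for c, s, e in intervals)
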