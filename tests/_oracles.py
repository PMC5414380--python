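"""Independent brute-force oracles used by the test suite.

Everything here is written with plain Python loops and the standard-library
calendar, deliberately avoiding the vectorised code paths of the package, so
that agreement between the two is evidence of correctness rather than of
shared bugs.
"""

from __future__ import annotations

import datetime
import math

DAYS_PER_YEAR = 365.241
EPOCH = datetime.date(1960, 1, 1)


def calendar_walk_hazard(rt, age_days, sex, entry_day, horizon):
    """Day-by-day population hazard path using datetime arithmetic."""
    out = []
    for u in range(1, horizon + 1):
        age_years = math.floor((age_days + u) / DAYS_PER_YEAR)
        date = EPOCH + datetime.timedelta(days=int(entry_day + u))
        ai = min(age_years, int(rt.ages[-1])) - int(rt.ages[0])
        yi = date.year - int(rt.years[0])
        out.append(float(rt.hazard[sex - 1, ai, yi]))
    return out


def pop_survival_path(rt, age_days, sex, entry_day, horizon):
    """S_P,i(u) for u = 1..horizon by direct summation."""
    path = calendar_walk_hazard(rt, age_days, sex, entry_day, horizon)
    out, acc = [], 0.0
    for lam in path:
        acc += lam
        out.append(math.exp(-acc))
    return out


def rs_diff_oracle(rt, time, status, group, age_days, sex, entry_day, tau):
    """Materialise every per-individual per-day term of the weighted test.

    Returns (Z, Sigma) over the full set of k group labels (Z length k,
    Sigma k x k), built from the estimated excess event / at-risk processes
    and the squared-weight plug-in covariance.
    """
    n = len(time)
    labels = sorted(set(group))
    k = len(labels)
    gidx = {g: i for i, g in enumerate(labels)}

    sp = [pop_survival_path(rt, age_days[i], sex[i], entry_day[i], tau)
          for i in range(n)]
    haz = [calendar_walk_hazard(rt, age_days[i], sex[i], entry_day[i], tau)
           for i in range(n)]

    Z = [0.0] * k
    Sigma = [[0.0] * k for _ in range(k)]
    for u in range(1, tau + 1):
        y = [0.0] * k
        dn = [0.0] * k
        w2 = 0.0
        for i in range(n):
            if time[i] < u:
                continue
            w = 1.0 / sp[i][u - 1]
            h = gidx[group[i]]
            y[h] += w
            dn[h] -= w * haz[i][u - 1]          # compensator increment
            if time[i] == u and status[i] == 1:
                dn[h] += w
                w2 += w * w
        ytot = sum(y)
        if ytot <= 0:
            continue
        dtot = sum(dn)
        p = [yi / ytot for yi in y]
        for h in range(k):
            Z[h] += dn[h] - p[h] * dtot
            for j in range(k):
                Sigma[h][j] += ((1.0 if h == j else 0.0) * p[h] - p[h] * p[j]) * w2
    return Z, Sigma


def logrank_oracle(time, status, group, tau, variance="hypergeometric"):
    """Classical log-rank by explicit per-day contingency tabulation."""
    labels = sorted(set(group))
    k = len(labels)
    gidx = {g: i for i, g in enumerate(labels)}
    Z = [0.0] * k
    V = [[0.0] * k for _ in range(k)]
    for u in range(1, tau + 1):
        y = [0] * k
        dn = [0] * k
        for i in range(len(time)):
            if time[i] >= u:
                y[gidx[group[i]]] += 1
                if time[i] == u and status[i] == 1:
                    dn[gidx[group[i]]] += 1
        ytot = sum(y)
        dtot = sum(dn)
        if ytot == 0 or dtot == 0:
            continue
        p = [yi / ytot for yi in y]
        if variance == "hypergeometric":
            factor = dtot * (ytot - dtot) / (ytot - 1) if ytot > 1 else 0.0
        else:
            factor = dtot
        for h in range(k):
            Z[h] += dn[h] - p[h] * dtot
            for j in range(k):
                V[h][j] += ((1.0 if h == j else 0.0) * p[h] - p[h] * p[j]) * factor
    return Z, V
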