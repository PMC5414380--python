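"""Excess-hazard weighted counting processes and the Pohar Perme curve.

Observable all-cause data (T_i, delta_i) cannot be split by cause of death.
To recover what would be seen in a hypothetical world where only the disease
kills, each individual's event and at-risk indicators are weighted by the
inverse of their population survival S_P,i(t) (read from a rate table), and
the expected number of population deaths among those at risk is subtracted:

    dN_E,i(t)-hat = dN_i(t) / S_P,i(t) - integral Y_E,i-hat(u) lambda_P,i(u) du
    Y_E,i(t)-hat  = Y_i(t) / S_P,i(t)

The subtracted integral (the compensator of population mortality) is a
continuous function of time, so everything is evaluated on a daily grid on
which lambda_P,i is constant; integrals become daily sums.  Group and stratum
aggregates of these processes are the raw material for the log-rank type test
and for the Pohar Perme net-survival estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import Cohort
from .ratetable import RateTable, hazard_path_matrix

__all__ = [
    "Cohort",
    "WeightedProcesses",
    "NetSurvivalCurve",
    "weighted_processes",
    "pohar_perme",
]


@dataclass
class WeightedProcesses:
    """Daily-grid aggregates of the PP-weighted processes.

    Arrays are indexed ``[stratum, group, day]`` with day ``u`` at index
    ``u - 1``; a cohort without strata has a single stratum 0.

    Attributes
    ----------
    y : ndarray (m, k, tau)
        Weighted at-risk process Y_E,h,s-hat(u).
    events : ndarray (m, k, tau)
        Weighted observed-event increments (nonzero only on death days).
    compensator : ndarray (m, k, tau)
        Daily expected population deaths among those at risk,
        sum_i Y_E,i-hat(u) * lambda_P,i(u).
    event_w2 : ndarray (m, tau)
        Squared-weight event increments sum_i S_P,i(T_i)^-2 dN_i(u), the
        per-stratum ingredient of the plug-in covariance of the test.
    n_strata, n_groups, tau : grid dimensions.
    """

    y: np.ndarray
    events: np.ndarray
    compensator: np.ndarray
    event_w2: np.ndarray
    tau: int
    group_labels: np.ndarray
    stratum_labels: np.ndarray
    events_per_stratum: np.ndarray     # raw death counts within tau
    groups_per_stratum: np.ndarray     # distinct group labels present
    stratum_sizes: np.ndarray
    cell_sizes: np.ndarray             # individuals per (stratum, group)

    @property
    def n_strata(self) -> int:
        return self.y.shape[0]

    @property
    def n_groups(self) -> int:
        return self.y.shape[1]

    def dn_excess(self) -> np.ndarray:
        """Estimated excess-event increments dN_E,h,s-hat = events - compensator."""
        return self.events - self.compensator

    def pooled(self):
        """(Y-hat, dN_E-hat, event_w2) summed over strata and groups."""
        return (
            self.y.sum(axis=(0, 1)),
            self.dn_excess().sum(axis=(0, 1)),
            self.event_w2.sum(axis=0),
        )


@dataclass
class NetSurvivalCurve:
    """Pohar Perme net survival on the daily grid (point estimate only)."""

    day: np.ndarray              # 0, 1, ..., tau_eff
    cum_excess_hazard: np.ndarray
    survival: np.ndarray

    def at(self, t: int) -> float:
        """Net survival at day t (step function, last value carried forward)."""
        idx = np.searchsorted(self.day, t, side="right") - 1
        return float(self.survival[idx])


# ---------------------------------------------------------------------------


def _population_weight_matrices(cohort: Cohort, rt: RateTable, tau: int):
    """Per-individual daily hazard H and inverse-survival weight W = 1/S_P.

    ``W[i, u-1] = exp(sum_{v<=u} H[i, v-1]) = 1 / S_P,i(u)``.
    """
    H = hazard_path_matrix(
        rt, cohort.age_at_entry, cohort.sex, cohort.entry_date, tau
    )
    W = np.exp(np.cumsum(H, axis=1))
    return H, W


def _aggregate(
    cohort: Cohort,
    H: np.ndarray,
    W: np.ndarray,
    tau: int,
    use_strata: bool,
) -> WeightedProcesses:
    """Sum per-individual weighted contributions into (stratum, group) cells."""
    n = cohort.n
    group = cohort.group if cohort.group is not None else np.zeros(n, dtype=int)
    glabels = np.unique(group)
    gcode = np.searchsorted(glabels, group)
    k = len(glabels)
    if use_strata and cohort.stratum is not None:
        slabels = np.unique(cohort.stratum)
        scode = np.searchsorted(slabels, cohort.stratum)
    else:
        slabels = np.array([0])
        scode = np.zeros(n, dtype=int)
    m = len(slabels)

    at_risk = np.arange(1, tau + 1)[None, :] <= cohort.time[:, None]
    Wr = W * at_risk                      # weighted at-risk indicator
    cell = scode * k + gcode

    order = np.argsort(cell, kind="stable")
    sorted_cells = cell[order]
    present, starts = np.unique(sorted_cells, return_index=True)

    y = np.zeros((m * k, tau))
    comp = np.zeros((m * k, tau))
    y[present] = np.add.reduceat(Wr[order], starts, axis=0)
    comp[present] = np.add.reduceat((Wr * H)[order], starts, axis=0)

    events = np.zeros((m * k, tau))
    event_w2 = np.zeros((m, tau))
    died = (cohort.status == 1) & (cohort.time <= tau)
    ti = cohort.time[died] - 1
    w_at_death = W[died, ti]
    np.add.at(events, (cell[died], ti), w_at_death)
    np.add.at(event_w2, (scode[died], ti), w_at_death**2)

    events_per_stratum = np.zeros(m, dtype=int)
    np.add.at(events_per_stratum, scode[died], 1)
    groups_per_stratum = np.array(
        [len(np.unique(gcode[scode == s])) for s in range(m)]
    )
    stratum_sizes = np.bincount(scode, minlength=m)
    cell_sizes = np.bincount(cell, minlength=m * k).reshape(m, k)

    return WeightedProcesses(
        y=y.reshape(m, k, tau),
        events=events.reshape(m, k, tau),
        compensator=comp.reshape(m, k, tau),
        event_w2=event_w2,
        tau=tau,
        group_labels=glabels,
        stratum_labels=slabels,
        events_per_stratum=events_per_stratum,
        groups_per_stratum=groups_per_stratum,
        stratum_sizes=stratum_sizes,
        cell_sizes=cell_sizes,
    )


def weighted_processes(
    cohort: Cohort,
    rt: RateTable,
    tau: Optional[int] = None,
    use_strata: bool = False,
) -> WeightedProcesses:
    """Build the PP-weighted at-risk / event / compensator processes.

    Each individual contributes, for every day ``u <= min(T_i, tau)``, a
    weighted at-risk term ``1/S_P,i(u)`` and a compensator term
    ``lambda_P,i(u)/S_P,i(u)``; deaths additionally contribute
    ``1/S_P,i(T_i)`` on the death day.  The compensator accumulates on the
    death day itself (a half-day correction would be O(lambda_P) per day and
    is absorbed by the one-day integration step).
    """
    if cohort.n == 0:
        raise ValueError("empty cohort")
    if tau is None:
        tau = int(cohort.time.max())
    H, W = _population_weight_matrices(cohort, rt, tau)
    return _aggregate(cohort, H, W, tau, use_strata)


def pohar_perme(
    cohort: Cohort, rt: RateTable, tau: Optional[int] = None
) -> NetSurvivalCurve:
    """Pohar Perme estimate of net survival, S_E(t) = exp(-Lambda_E(t)-hat).

    The cumulative excess hazard accumulates dN_E-hat(u) / Y_E-hat(u) over
    days with a nonempty weighted risk set; the curve is truncated at the
    first day the pooled risk set empties.
    """
    wp = weighted_processes(cohort, rt, tau=tau, use_strata=False)
    y, dn, _ = wp.pooled()
    positive = y > 0
    if not positive.all():
        first_empty = int(np.argmin(positive))  # first False
        y, dn = y[:first_empty], dn[:first_empty]
    lam = np.where(y > 0, dn / np.where(y > 0, y, 1.0), 0.0)
    cum = np.concatenate([[0.0], np.cumsum(lam)])
    day = np.arange(len(cum))
    return NetSurvivalCurve(day=day, cum_excess_hazard=cum, survival=np.exp(-cum))
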