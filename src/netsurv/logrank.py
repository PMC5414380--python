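"""Log-rank tests for net survival: classical, and the log-rank type test.

Two settings share one observed-minus-expected skeleton:

* :func:`logrank` -- the classical (optionally stratified) k-sample log-rank
  test, applicable when cause-specific data are available (in simulations,
  the hypothetical-world data).

* :func:`rs_diff` -- the log-rank type test on real-world all-cause data,
  where events and risk sets are replaced by their Pohar Perme weighted
  estimates and the integral runs over a daily grid because the population
  compensator is continuous in time.

Both produce a vector Z of per-group observed-minus-expected sums, an
estimated covariance, and the quadratic-form statistic U = Z' Sigma^-1 Z,
asymptotically chi-square with k-1 degrees of freedom under the null of
equal (excess) hazards.  Stratified versions sum Z and Sigma over strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg, stats

from .cohort import Cohort
from .processes import WeightedProcesses, weighted_processes
from .ratetable import RateTable

logger = logging.getLogger(__name__)

__all__ = ["TestResult", "logrank", "rs_diff", "chi2_pvalue"]


@dataclass
class TestResult:
    """Result of a k-sample (stratified) log-rank style test.

    ``z_full`` has one entry per group and sums to zero; ``Z`` drops the
    last group and is the vector entering the quadratic form with
    covariance ``Sigma``.
    """

    group_labels: np.ndarray
    z_full: np.ndarray
    Z: np.ndarray
    Sigma: np.ndarray
    U: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray
    group_sizes: np.ndarray
    tau: int
    n: int
    n_strata_used: int = 1
    n_strata_dropped: int = 0
    n_excluded: int = 0
    warnings: list = field(default_factory=list)

    def __str__(self) -> str:  # survdiff-style report
        lines = [f"{'group':>8} {'N':>6} {'observed':>10} {'expected':>10}"]
        lines.extend(
            f"{g!s:>8} {c:>6} {o:>10.2f} {e:>10.2f}"
            for g, c, o, e in zip(
                self.group_labels, self.group_sizes, self.observed, self.expected
            )
        )
        zs = ", ".join(f"{z:+.3f}" for z in self.Z)
        vs = ", ".join(f"{v:.3f}" for v in np.diag(np.atleast_2d(self.Sigma)))
        lines.append(f"\nZ = ({zs});  var diag = ({vs})")
        lines.append(
            f"Chisq = {self.U:.3f} on {self.df} degrees of freedom, "
            f"p = {self.p:.4g}"
        )
        if self.n_strata_dropped:
            lines.append(
                f"({self.n_strata_dropped} strata without events or with a "
                f"single group dropped; {self.n_excluded} individuals excluded)"
            )
        return "\n".join(lines)


def chi2_pvalue(Z: np.ndarray, Sigma: np.ndarray):
    """Quadratic form U = Z' Sigma^-1 Z and its chi-square p-value.

    Uses a linear solve when Sigma is (numerically) full rank; otherwise a
    pseudo-inverse with the degrees of freedom reduced to the rank (relative
    eigenvalue cutoff 1e-10).
    """
    Z = np.atleast_1d(np.asarray(Z, dtype=float))
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    scale = max(1.0, float(np.abs(Sigma).max()))
    if np.abs(Sigma - Sigma.T).max() > 1e-8 * scale:
        raise ValueError("covariance matrix is not symmetric")
    evals = linalg.eigvalsh(Sigma)
    rank = int((evals > 1e-10 * max(evals.max(), 0) ).sum()) if evals.size else 0
    if rank == 0:
        return 0.0, 0, 1.0
    if rank == Sigma.shape[0]:
        U = float(Z @ linalg.solve(Sigma, Z, assume_a="pos"))
        df = rank
    else:
        U = float(Z @ linalg.pinvh(Sigma) @ Z)
        df = rank
    U = max(U, 0.0)
    return U, df, float(stats.chi2.sf(U, df))


# ---------------------------------------------------------------------------
# shared observed-minus-expected core


def _zs_from_processes(wp: WeightedProcesses, variance: str):
    """Per-stratum Z vectors and covariances from (weighted) daily processes.

    ``variance`` selects the per-day covariance kernel applied to the event
    mass w2(u) (= dN(u) for unweighted data, sum of squared individual
    weights for PP-weighted data):

    - ``martingale``:      (d_hj p_h - p_h p_j) * w2(u)
    - ``hypergeometric``:  same, times the ties factor (Y - dN)/(Y - 1)
      (unweighted data only).
    """
    m, k, tau = wp.y.shape
    dn = wp.dn_excess()
    Zs = np.zeros((m, k))
    Vs = np.zeros((m, k, k))
    keep = (wp.events_per_stratum >= 1) & (wp.groups_per_stratum >= 2)
    if m == 1:
        keep[:] = wp.events_per_stratum >= 1
    for s in range(m):
        if not keep[s]:
            continue
        y = wp.y[s]                      # (k, tau)
        ytot = y.sum(axis=0)
        valid = ytot > 0
        dns = dn[s][:, valid]
        ys = y[:, valid]
        ytot_v = ytot[valid]
        p = ys / ytot_v
        dtot = dns.sum(axis=0)
        Zs[s] = (dns - p * dtot).sum(axis=1)
        # covariance only accrues on event days
        w2 = wp.event_w2[s][valid]
        ev = w2 > 0
        pe = p[:, ev]
        w2e = w2[ev]
        if variance == "hypergeometric":
            ye = ytot_v[ev]
            de = wp.events[s][:, valid].sum(axis=0)[ev]
            ties = np.where(ye > 1, (ye - de) / np.maximum(ye - 1, 1.0), 0.0)
            w2e = w2e * ties
        V = -np.einsum("hu,ju,u->hj", pe, pe, w2e)
        V[np.diag_indices(k)] += pe @ w2e
        Vs[s] = V
    return Zs, Vs, keep


def _assemble(
    wp: WeightedProcesses, variance: str, tau: int, n: int
) -> TestResult:
    k = wp.n_groups
    if k < 2:
        raise ValueError("need at least 2 groups to compare")
    Zs, Vs, keep = _zs_from_processes(wp, variance)
    n_dropped = int((~keep).sum())
    n_excluded = int(wp.stratum_sizes[~keep].sum())
    if n_dropped:
        logger.info(
            "%d strata without events or with a single group dropped "
            "(%d individuals excluded)", n_dropped, n_excluded,
        )
    if not keep.any():
        raise ValueError("no stratum retains >=1 event and >=2 groups")
    z_full = Zs[keep].sum(axis=0)
    Sigma_full = Vs[keep].sum(axis=0)
    Z = z_full[:-1]
    Sigma = Sigma_full[:-1, :-1]
    warnings_list = []
    U, df, p = chi2_pvalue(Z, Sigma)
    if df < k - 1:
        warnings_list.append(
            f"singular covariance: rank {df} < {k - 1}, pseudo-inverse used"
        )
        logger.warning(warnings_list[-1])
    observed = wp.dn_excess()[keep].sum(axis=(0, 2))
    expected = observed - z_full
    return TestResult(
        group_labels=wp.group_labels,
        z_full=z_full,
        Z=Z,
        Sigma=Sigma,
        U=U,
        df=df,
        p=p,
        observed=observed,
        expected=expected,
        group_sizes=wp.cell_sizes[keep].sum(axis=0),
        tau=tau,
        n=n,
        n_strata_used=int(keep.sum()),
        n_strata_dropped=n_dropped,
        n_excluded=n_excluded,
        warnings=warnings_list,
    )


# ---------------------------------------------------------------------------
# public tests


def _unweighted_processes(cohort: Cohort, tau: int, use_strata: bool):
    """Unit-weight processes on the event-day grid.

    With no population weighting the compensator vanishes and dN is
    supported on event days only, so the integrals collapse to sums over
    the distinct death days; Y is evaluated there by rank queries instead
    of materialising the daily grid.
    """
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

    died = (cohort.status == 1) & (cohort.time <= tau)
    ev_days = np.unique(cohort.time[died])
    ne = max(len(ev_days), 1)
    y = np.zeros((m, k, ne))
    events = np.zeros((m, k, ne))
    event_w2 = np.zeros((m, ne))
    ev_idx = np.searchsorted(ev_days, cohort.time)
    for s in range(m):
        for h in range(k):
            sel = (scode == s) & (gcode == h)
            if not sel.any():
                continue
            t_sorted = np.sort(cohort.time[sel])
            y[s, h] = len(t_sorted) - np.searchsorted(t_sorted, ev_days, "left")
            dsel = sel & died
            np.add.at(events[s, h], ev_idx[dsel], 1.0)
        np.add.at(event_w2[s], ev_idx[(scode == s) & died], 1.0)

    events_per_stratum = np.zeros(m, dtype=int)
    np.add.at(events_per_stratum, scode[died], 1)
    groups_per_stratum = np.array(
        [len(np.unique(gcode[scode == s])) for s in range(m)]
    )
    return WeightedProcesses(
        y=y,
        events=events,
        compensator=np.zeros_like(y),
        event_w2=event_w2,
        tau=tau,
        group_labels=glabels,
        stratum_labels=slabels,
        events_per_stratum=events_per_stratum,
        groups_per_stratum=groups_per_stratum,
        stratum_sizes=np.bincount(scode, minlength=m),
        cell_sizes=np.bincount(scode * k + gcode, minlength=m * k).reshape(m, k),
    )


def logrank(
    cohort: Cohort,
    strata: bool = False,
    tau: Optional[int] = None,
    variance: str = "hypergeometric",
) -> TestResult:
    """Classical k-sample log-rank test (optionally stratified).

    ``variance='hypergeometric'`` applies the standard ties-corrected
    per-day covariance; ``'martingale'`` omits the ties factor.
    """
    if variance not in ("hypergeometric", "martingale"):
        raise ValueError(f"unknown variance {variance!r}")
    if tau is None:
        tau = int(cohort.time.max())
    wp = _unweighted_processes(cohort, tau, use_strata=strata)
    return _assemble(wp, variance, tau, cohort.n)


def rs_diff(
    cohort: Cohort,
    rt: RateTable,
    strata: bool = False,
    tau: Optional[int] = None,
) -> TestResult:
    """Log-rank type test comparing net survival on real-world data.

    Events and risk sets are inverse-population-survival weighted and the
    population compensator is subtracted, all on a daily grid.  The
    covariance is the plug-in estimator

        Sigma_hj = sum_u (d_hj p_h(u) - p_h(u) p_j(u)) * sum_i S_P,i(u)^-2 dN_i(u)

    with p_h the weighted at-risk fractions; with unit weights it reduces
    exactly to the martingale-form log-rank covariance.  Strata without
    events or with a single group at risk are dropped (with a logged count
    of excluded individuals).
    """
    if tau is None:
        tau = int(cohort.time.max())
    wp = weighted_processes(cohort, rt, tau=tau, use_strata=strata)
    return _assemble(wp, "martingale", tau, cohort.n)


def rs_diff_from_processes(wp: WeightedProcesses, n: int) -> TestResult:
    """Log-rank type test from precomputed weighted processes.

    Lets callers (the simulator) reuse one set of daily matrices for the
    stratified and non-stratified versions.
    """
    return _assemble(wp, "martingale", wp.tau, n)
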