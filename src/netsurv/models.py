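"""Fully parametric additive excess-hazard model.

The observed all-cause hazard is modelled as the known population hazard
plus a proportional excess part with a piecewise-constant baseline:

    lambda_O(t, x) = lambda_P(t, x) + lambda_E0(t) * exp(x' beta),
    lambda_E0(t) = exp(xi_j)  for t in interval j.

The population term is fully known from the rate table, so the ``integral
of lambda_P`` piece of the log likelihood is parameter free and drops out;
the model only needs lambda_P at each death time.  Maximisation is by
quasi-Newton on (xi, beta) with analytic gradients; the covariance is the
inverse observed information (numerical Hessian of the negative log
likelihood).  The Wald test on a covariate coefficient is the comparator
test for differences in net survival between groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from ._calendar import DAYS_PER_YEAR, year_of_day
from .cohort import Cohort
from .ratetable import RateTable

__all__ = ["FAMFit", "fit_fam", "wald_test"]

#: default single baseline interval: (0, 10 years]
DEFAULT_BREAKPOINTS = (3652,)


@dataclass
class FAMFit:
    """Maximum-likelihood fit of the additive excess-hazard model."""

    breakpoints: np.ndarray       # interval right endpoints, days
    xi: np.ndarray                # log baseline excess hazard per interval
    beta: np.ndarray              # covariate coefficients
    names: list                   # covariate names
    cov: np.ndarray               # covariance of (xi, beta)
    loglik: float
    converged: bool
    grad_norm: float
    n_iter: int

    @property
    def baseline(self) -> np.ndarray:
        """Baseline excess hazard per interval (per day)."""
        return np.exp(self.xi)

    def se(self, name: str) -> float:
        j = len(self.xi) + self.names.index(name)
        return float(np.sqrt(self.cov[j, j]))

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])


def _exposure(time: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Days at risk of each individual within each baseline interval."""
    lo = np.concatenate([[0], edges[:-1]])
    return np.clip(np.minimum(time[:, None], edges[None, :]) - lo[None, :], 0, None)


def _neg_loglik_and_grad(theta, J, X, delta, lamP_death, death_interval, expo):
    xi, beta = theta[:J], theta[J:]
    eta = X @ beta if X.size else np.zeros(len(delta))
    ex_eta = np.exp(eta)
    lamE0 = np.exp(xi)
    # event part
    mu = lamE0[death_interval] * ex_eta      # excess hazard at own death time
    denom = lamP_death + mu
    died = delta == 1
    ll = np.log(denom[died]).sum()
    # cumulative part: sum_i e^eta_i * sum_j lamE0_j * expo_ij
    cum_i = expo @ lamE0
    ll -= float(ex_eta @ cum_i)

    ratio = np.where(died, mu / denom, 0.0)
    g_xi = np.zeros(J)
    np.add.at(g_xi, death_interval[died], ratio[died])
    g_xi -= (ex_eta[:, None] * expo * lamE0[None, :]).sum(axis=0)
    if X.size:
        g_beta = X[died].T @ ratio[died] - X.T @ (ex_eta * cum_i)
    else:
        g_beta = np.zeros(0)
    return -ll, -np.concatenate([g_xi, g_beta])


def fit_fam(
    cohort: Cohort,
    rt: Optional[RateTable],
    x: Optional[np.ndarray] = None,
    names: Optional[Sequence[str]] = None,
    breakpoints: Sequence[int] = DEFAULT_BREAKPOINTS,
    max_iter: int = 500,
) -> FAMFit:
    """Fit the additive model by maximum likelihood.

    Parameters
    ----------
    cohort : Cohort
    rt : RateTable or None
        Population table; ``None`` means lambda_P = 0 (pure exponential
        regression, useful for validation).
    x : (n, p) design matrix for the excess-hazard covariates (no
        intercept; the baseline absorbs it).  ``None`` fits baseline only.
    names : covariate names (defaults to x0, x1, ...).
    breakpoints : increasing right endpoints (days) of the baseline
        intervals; the last interval is extended to cover the longest
        follow-up if needed.
    """
    time = cohort.time.astype(float)
    delta = cohort.status
    edges = np.asarray(sorted(breakpoints), dtype=float)
    if edges[-1] < time.max():
        edges = edges.copy()
        edges[-1] = time.max()
    J = len(edges)
    if x is None:
        X = np.zeros((cohort.n, 0))
    else:
        X = np.atleast_2d(np.asarray(x, dtype=float))
        if X.shape[0] != cohort.n:
            X = X.T
    p = X.shape[1]
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]
    if len(names) != p:
        raise ValueError("names length must match design columns")

    expo = _exposure(time, edges)
    if (expo.sum(axis=0) <= 0).any():
        raise ValueError("every baseline interval needs >0 person-days at risk")
    death_interval = np.searchsorted(edges, time, side="left")
    death_interval = np.minimum(death_interval, J - 1)

    if rt is None:
        lamP_death = np.zeros(cohort.n)
    else:
        u = cohort.time
        lamP_death = rt.lookup(
            cohort.sex,
            ((cohort.age_at_entry + u) / DAYS_PER_YEAR).astype(int),
            year_of_day(cohort.entry_date + u),
        )

    # init: overall crude event rate on the log scale, beta = 0
    rate0 = max(delta.sum(), 0.5) / time.sum()
    theta0 = np.concatenate([np.full(J, np.log(rate0)), np.zeros(p)])
    args = (J, X, delta, lamP_death, death_interval, expo)
    res = optimize.minimize(
        _neg_loglik_and_grad,
        theta0,
        args=args,
        jac=True,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": max_iter},
    )
    theta = res.x
    nll, grad = _neg_loglik_and_grad(theta, *args)
    nparam = J + p

    def _fd_hessian(th):
        hess = np.zeros((nparam, nparam))
        h = 1e-6 * np.maximum(1.0, np.abs(th))
        for i in range(nparam):
            tp, tm = th.copy(), th.copy()
            tp[i] += h[i]
            tm[i] -= h[i]
            hess[i] = (
                _neg_loglik_and_grad(tp, *args)[1]
                - _neg_loglik_and_grad(tm, *args)[1]
            ) / (2 * h[i])
        return (hess + hess.T) / 2

    # Newton polish: BFGS stops on relative precision; a few damped Newton
    # steps with the observed information drive the gradient to ~1e-6
    hess = _fd_hessian(theta)
    for _ in range(5):
        if np.abs(grad).max() < 1e-6:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(20):
            cand = theta - scale * step
            nll_c, grad_c = _neg_loglik_and_grad(cand, *args)
            if nll_c <= nll:
                theta, nll, grad = cand, nll_c, grad_c
                break
            scale /= 2
        else:
            break
        hess = _fd_hessian(theta)

    grad_norm = float(np.abs(grad).max())
    converged = grad_norm < 1e-4
    try:
        cov = np.linalg.inv(hess)
        if (np.diag(cov)[J:] <= 0).any():
            converged = False
    except np.linalg.LinAlgError:
        cov = np.full((nparam, nparam), np.nan)
        converged = False

    return FAMFit(
        breakpoints=edges,
        xi=theta[:J],
        beta=theta[J:],
        names=names,
        cov=cov,
        loglik=-nll,
        converged=converged,
        grad_norm=grad_norm,
        n_iter=res.nit,
    )


def wald_test(fit: FAMFit, coefficient: str):
    """Two-sided Wald test of H0: beta = 0 for one covariate.

    Returns ``(z, p)``.  Baseline parameters cannot be tested this way.
    """
    if coefficient not in fit.names:
        raise ValueError(
            f"{coefficient!r} is not a covariate of this fit "
            f"(baseline parameters cannot be Wald-tested); have {fit.names}"
        )
    if not fit.converged:
        raise ValueError("model fit did not converge; Wald test unavailable")
    z = fit.coef(coefficient) / fit.se(coefficient)
    return float(z), float(2 * stats.norm.sf(abs(z)))
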