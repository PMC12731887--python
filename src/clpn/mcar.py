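"""Little's MCAR test over missingness patterns.

The test compares, for every distinct missingness pattern, the mean of the
observed variables in that pattern with the pooled maximum-likelihood mean,
scaled by the pooled ML covariance:

    d2 = sum_p  n_p (xbar_{p,obs} - mu_obs)' Sigma_obs^{-1} (xbar_{p,obs} - mu_obs)

with df = (sum_p k_p) - k, where k_p is the number of observed variables in
pattern p and k the total number of variables.  mu and Sigma are estimated
by EM under a multivariate-normal model using all patterns jointly.  Under
MCAR, d2 is asymptotically chi-square(df).

The study design this package targets has wave-2 dropout only (two
patterns: fully observed, and T1-only), but the implementation is general
over arbitrary patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError
from .panel import PanelDataset


@dataclass(frozen=True)
class LittleMCARResult:
    statistic: float
    df: int
    p_value: float
    n_patterns: int


def _em_mvnorm(
    X: np.ndarray, max_iter: int = 200, tol: float = 1e-7
) -> tuple[np.ndarray, np.ndarray]:
    """ML mean/covariance of a multivariate normal with missing values.

    Pattern-grouped EM; covariance is the ML (1/n) estimate.  A small ridge
    keeps conditioning safe when some variable is nearly collinear.
    """
    n, p = X.shape
    obs = ~np.isnan(X)
    mu = np.array([np.nanmean(X[:, j]) for j in range(p)])
    var = np.array([np.nanvar(X[:, j]) for j in range(p)])
    var[var <= 0] = 1.0
    sigma = np.diag(var)
    complete = obs.all(axis=1)
    if complete.sum() > p + 1:
        sigma = np.cov(X[complete].T, bias=True)
        sigma[np.diag_indices_from(sigma)] += 1e-8 * np.trace(sigma) / p

    patterns = {}
    for i in range(n):
        patterns.setdefault(obs[i].tobytes(), []).append(i)
    groups = [
        (np.frombuffer(key, dtype=bool), np.array(idx))
        for key, idx in patterns.items()
    ]

    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for o, idx in groups:
            Xg = X[idx]
            m = ~o
            if m.any():
                Soo = sigma[np.ix_(o, o)]
                Som = sigma[np.ix_(o, m)]
                Smm = sigma[np.ix_(m, m)]
                B = np.linalg.solve(Soo, Som)  # (k_o, k_m)
                resid = Xg[:, o] - mu[o]
                Xg = Xg.copy()
                Xg[:, m] = mu[m] + resid @ B
                cond_cov = Smm - Som.T @ B
            else:
                cond_cov = None
            sum_x += Xg.sum(axis=0)
            cp = Xg.T @ Xg
            if cond_cov is not None:
                add = np.zeros((p, p))
                add[np.ix_(m, m)] = len(idx) * cond_cov
                cp = cp + add
            sum_xx += cp
        mu_new = sum_x / n
        sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        sigma_new[np.diag_indices_from(sigma_new)] += 1e-10 * np.trace(
            sigma_new
        ) / p
        shift = np.max(np.abs(mu_new - mu)) + np.max(np.abs(sigma_new - sigma))
        mu, sigma = mu_new, sigma_new
        if shift < tol:
            break
    return mu, sigma


def little_mcar_test(data: PanelDataset | pd.DataFrame) -> LittleMCARResult:
    """Little's chi-square test of missing-completely-at-random.

    Accepts a :class:`PanelDataset` (analysis variables are used) or a plain
    numeric DataFrame.  Requires at least two distinct missingness patterns.
    """
    if isinstance(data, PanelDataset):
        X = data.values.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    keep = obs.any(axis=1)
    X, obs = X[keep], obs[keep]

    keys = {}
    for i in range(len(X)):
        keys.setdefault(obs[i].tobytes(), []).append(i)
    if len(keys) < 2:
        raise DegenerateDataError(
            "need at least two distinct missingness patterns"
        )

    mu, sigma = _em_mvnorm(X)
    d2 = 0.0
    sum_k = 0
    for key, idx in keys.items():
        o = np.frombuffer(key, dtype=bool)
        xbar = X[np.ix_(idx, np.flatnonzero(o))].mean(axis=0)
        diff = xbar - mu[o]
        Soo = sigma[np.ix_(o, o)]
        d2 += len(idx) * float(diff @ np.linalg.solve(Soo, diff))
        sum_k += int(o.sum())
    df = sum_k - p
    if df < 1:
        raise DegenerateDataError("zero degrees of freedom for Little's test")
    return LittleMCARResult(d2, df, float(stats.chi2.sf(d2, df)), len(keys))
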