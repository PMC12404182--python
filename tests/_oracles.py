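"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
implementation: daily expansion instead of the monthly closed form, direct
numerical maximization of the REML objective instead of statsmodels, and
exhaustive search over contiguous 1-D partitions instead of Lloyd iteration.
"""

from __future__ import annotations

import calendar as _cal
import itertools

import numpy as np
from scipy import optimize

_FIXED_365 = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


def daily_expansion_degree_days(tas_by_month, year, base_c, calendar="gregorian"):
    """Brute-force annual degree days: replicate each month's mean over its
    days, clamp at the base, and sum day by day."""
    total = 0.0
    for month, tas in zip(range(1, 13), tas_by_month):
        if calendar == "fixed_365":
            n = _FIXED_365[month - 1]
        else:
            n = _cal.monthrange(year, month)[1]
        for _ in range(n):
            total += max(0.0, tas - base_c)
    return total


def reml_neg_loglike(theta, y, t, groups_idx):
    """Negative REML log-likelihood of a random-intercept/random-slope model.

    theta = [log sd_b0, log sd_b1, atanh rho, log sigma]; the REML constant
    -0.5 (n - p) log(2 pi) is included so values are comparable with
    statsmodels' REML ``llf``.
    """
    sd0, sd1 = np.exp(theta[0]), np.exp(theta[1])
    rho = np.tanh(theta[2])
    sig2 = np.exp(2 * theta[3])
    S = np.array([[sd0**2, rho * sd0 * sd1], [rho * sd0 * sd1, sd1**2]])
    XtViX = np.zeros((2, 2))
    XtViy = np.zeros(2)
    logdetV = 0.0
    cache = []
    for idx in groups_idx:
        ti, yi = t[idx], y[idx]
        Z = np.column_stack([np.ones_like(ti), ti])
        V = Z @ S @ Z.T + sig2 * np.eye(len(ti))
        c = np.linalg.cholesky(V)
        logdetV += 2 * np.sum(np.log(np.diag(c)))
        XtViX += Z.T @ np.linalg.solve(V, Z)
        XtViy += Z.T @ np.linalg.solve(V, yi)
        cache.append((yi, Z, V))
    beta = np.linalg.solve(XtViX, XtViy)
    quad = sum(
        (yi - Z @ beta) @ np.linalg.solve(V, yi - Z @ beta) for yi, Z, V in cache
    )
    _, logdetXtViX = np.linalg.slogdet(XtViX)
    n, p = len(y), 2
    ll = -0.5 * (logdetV + logdetXtViX + quad) - 0.5 * (n - p) * np.log(2 * np.pi)
    return -ll, beta


def fit_reml_oracle(y, t, groups_idx, x0=None):
    """Maximize the REML objective with a general-purpose optimizer."""
    f = lambda th: reml_neg_loglike(th, y, t, groups_idx)[0]
    if x0 is None:
        x0 = np.array([np.log(0.3), np.log(0.01), 0.0, np.log(0.1)])
    r = optimize.minimize(
        f, x0, method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-12, maxiter=4000, maxfev=6000),
    )
    r = optimize.minimize(
        f, r.x, method="Nelder-Mead",
        options=dict(xatol=1e-12, fatol=1e-14, maxiter=4000, maxfev=6000),
    )
    nll, beta = reml_neg_loglike(r.x, y, t, groups_idx)
    th = r.x
    return dict(
        fixed_intercept=beta[0],
        fixed_slope=beta[1],
        var_b0=np.exp(2 * th[0]),
        var_b1=np.exp(2 * th[1]),
        cov_b0b1=np.tanh(th[2]) * np.exp(th[0] + th[1]),
        sigma2=np.exp(2 * th[3]),
        loglike=-nll,
    )


def best_contiguous_3partition(values):
    """Optimal 1-D 3-clustering by exhaustive search over contiguous splits.

    The optimal k-means partition of 1-D data is contiguous in sorted order,
    so searching all C(n-1, 2) split-point pairs is exact.  Returns the
    minimal within-cluster sum of squares.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def wss(seg):
        return float(((seg - seg.mean()) ** 2).sum()) if len(seg) else 0.0

    best = np.inf
    for i, j in itertools.combinations(range(1, n), 2):
        best = min(best, wss(x[:i]) + wss(x[i:j]) + wss(x[j:]))
    return best
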