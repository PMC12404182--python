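"""Velocity of thermal change from random-slope linear mixed models.

For one mountain range, annual GDD (ln(x+1)-transformed) or annual mean
temperature (log(x+10)-transformed) is regressed on year with a fixed year
effect and a watershed-level random intercept and random slope, estimated by
REML with an unstructured 2x2 random-effect covariance.  Each watershed's
velocity of change is its total slope — the fixed year effect plus its BLUP
slope deviation — on the transformed scale per calendar year.  Fit quality
is summarized by marginal/conditional pseudo-R2 instead of random-effect
p-values; velocities are compared across elevation (Pearson) and across
ranges (one-way ANOVA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, ModelError

__all__ = [
    "transform_response",
    "inverse_transform",
    "MixedModelFit",
    "fit_random_slope_model",
    "extract_velocities",
    "pseudo_r2",
    "velocity_elevation_correlation",
    "compare_ranges_anova",
]

_BOUNDARY_TOL = 1e-8


def transform_response(x, kind: str = "ln_gdd_plus1", base: str = "e"):
    """Variance-stabilizing response transforms.

    ``ln_gdd_plus1``: log(x + 1) for degree days (x >= 0, so log is defined
    and zero maps to zero).  ``log_temp_plus10``: log(x + 10), shifting mean
    temperatures positive before the logarithm (requires x > -10).
    ``base`` is "e" (natural, default) or "10"; the choice rescales slopes
    by a constant and leaves correlations and ANOVA F unchanged.
    """
    arr = np.asarray(x, dtype=float)
    if kind == "ln_gdd_plus1":
        if np.any(arr < 0):
            raise DomainError("ln_gdd_plus1 requires x >= 0")
        out = np.log1p(arr)
    elif kind == "log_temp_plus10":
        if np.any(arr <= -10):
            raise DomainError("log_temp_plus10 requires x > -10")
        out = np.log(arr + 10.0)
    else:
        raise DomainError(f"unknown transform {kind!r}")
    if base == "10":
        out = out / np.log(10.0)
    elif base != "e":
        raise DomainError("base must be 'e' or '10'")
    return out if out.ndim else float(out)


def inverse_transform(y, kind: str = "ln_gdd_plus1", base: str = "e"):
    arr = np.asarray(y, dtype=float)
    if base == "10":
        arr = arr * np.log(10.0)
    if kind == "ln_gdd_plus1":
        out = np.expm1(arr)
    elif kind == "log_temp_plus10":
        out = np.exp(arr) - 10.0
    else:
        raise DomainError(f"unknown transform {kind!r}")
    return out if out.ndim else float(out)


@dataclass
class MixedModelFit:
    """REML fit of transformed response ~ year with watershed random slopes."""

    region: str
    transform: str
    fixed_intercept: float  # at the centered-year origin (sample mean year)
    fixed_slope_per_yr: float
    random_effects: pd.DataFrame  # watershed_id, b0, b1 (BLUP deviations)
    var_b0: float
    var_b1: float
    cov_b0b1: float
    sigma2: float
    criterion_value: float  # REML log-likelihood at the optimum
    converged: bool
    boundary: bool  # a variance component estimated at (numerical) zero
    year_mean: float
    mean_yc2: float  # mean of squared centered year over observations
    var_fixed_pred: float  # population variance of fixed-effect predictions
    n_groups: int = 0
    n_obs: int = 0
    log_base: str = "e"
    _summary: dict = field(default_factory=dict, repr=False)


def fit_random_slope_model(
    dd: pd.DataFrame,
    transform: str = "ln_gdd_plus1",
    response: str = "gdd",
    region: str = "",
    log_base: str = "e",
) -> MixedModelFit:
    """Fit the per-range random-slope model by REML.

    ``dd`` needs columns ``watershed_id``, ``year`` and the response
    (default annual ``gdd``).  The year covariate is centered at its sample
    mean for numerical stability; reported slopes are per calendar year.
    Requires >= 2 watersheds with >= 3 years each; rows with missing values
    are dropped.  Boundary fits (zero variance estimates) are flagged, not
    rejected — degenerate data legitimately produce them.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    d = dd[["watershed_id", "year", response]].dropna()
    n_years = d.groupby("watershed_id")["year"].nunique()
    if len(n_years) < 2:
        raise ModelError("random-slope model needs >= 2 watersheds")
    if (n_years < 3).any():
        bad = n_years[n_years < 3].index.tolist()
        raise ModelError(f"watershed(s) with < 3 years: {bad}")

    y = transform_response(d[response].to_numpy(), transform, base=log_base)
    year = d["year"].to_numpy(dtype=float)
    year_mean = year.mean()
    yc = year - year_mean
    exog = np.column_stack([np.ones_like(yc), yc])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary/convergence warnings handled via flags
        model = MixedLM(y, exog, groups=d["watershed_id"].to_numpy(), exog_re=exog)
        res = None
        for method in ("bfgs", "lbfgs", "powell"):
            try:
                cand = model.fit(reml=True, method=method, maxiter=5000)
            except Exception:
                continue
            if res is None or (cand.converged and not res.converged) or (
                cand.converged == res.converged and cand.llf > res.llf
            ):
                res = cand
            if res.converged:
                break
        if res is None:
            raise ModelError("mixed-model optimization failed with every optimizer")

    cov_re = np.asarray(res.cov_re, dtype=float)
    var_b0, var_b1 = float(cov_re[0, 0]), float(cov_re[1, 1])
    cov_b0b1 = float(cov_re[0, 1])
    sigma2 = float(res.scale)

    re = res.random_effects
    wids = sorted(re.keys())
    b = np.array([np.asarray(re[w], dtype=float) for w in wids])
    random_effects = pd.DataFrame(
        {"watershed_id": wids, "b0": b[:, 0], "b1": b[:, 1]}
    )

    slope = float(res.fe_params[1])
    var_fixed = float(np.var(slope * yc))  # intercept adds no variance
    scale_ref = max(float(np.var(y)), 1e-12)
    boundary = (
        var_b0 <= _BOUNDARY_TOL * scale_ref
        or var_b1 <= _BOUNDARY_TOL * scale_ref / max(yc.var(), 1.0)
        or sigma2 <= _BOUNDARY_TOL * scale_ref
    )
    return MixedModelFit(
        region=region,
        transform=transform,
        fixed_intercept=float(res.fe_params[0]),
        fixed_slope_per_yr=slope,
        random_effects=random_effects,
        var_b0=var_b0,
        var_b1=var_b1,
        cov_b0b1=cov_b0b1,
        sigma2=sigma2,
        criterion_value=float(res.llf),
        converged=bool(res.converged),
        boundary=bool(boundary),
        year_mean=float(year_mean),
        mean_yc2=float(np.mean(yc**2)),
        var_fixed_pred=var_fixed,
        n_groups=int(len(wids)),
        n_obs=int(len(d)),
        log_base=log_base,
    )


def extract_velocities(
    fit: MixedModelFit, watersheds: pd.DataFrame, mode: str = "total"
) -> pd.DataFrame:
    """Per-watershed velocity of change on the transformed scale.

    ``total`` (default): fixed slope + BLUP slope deviation, the watershed's
    own trend.  ``deviation``: BLUP deviation only (mean-zero by
    construction), kept as an option.
    """
    if mode not in ("total", "deviation"):
        raise DomainError("mode must be 'total' or 'deviation'")
    v = fit.random_effects["b1"].to_numpy()
    if mode == "total":
        v = v + fit.fixed_slope_per_yr
    out = pd.DataFrame(
        {"watershed_id": fit.random_effects["watershed_id"], "velocity": v}
    )
    return out.merge(
        watersheds[["watershed_id", "region", "elevation_m"]], on="watershed_id"
    )


def pseudo_r2(fit: MixedModelFit) -> tuple[float, float]:
    """Marginal and conditional pseudo-R2 of a mixed-model fit.

    Marginal: variance of fixed-effect predictions over total variance.
    Conditional: fixed plus random-effect variance over total.  The
    random-slope contribution uses the design-averaged formulation,
    mean over observations of z' Sigma z with z = (1, centered year).
    """
    var_f = fit.var_fixed_pred
    # mean(yc) = 0 by construction; the cross term with cov_b0b1 vanishes
    var_r = fit.var_b0 + fit.var_b1 * fit.mean_yc2
    total = var_f + var_r + fit.sigma2
    if total <= 0:
        raise DomainError("total variance is zero; pseudo-R2 undefined")
    return var_f / total, (var_f + var_r) / total


def velocity_elevation_correlation(velocities: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of velocity against elevation with two-sided p."""
    if len(velocities) < 3:
        raise DomainError("need >= 3 watersheds for a correlation")
    v = velocities["velocity"].to_numpy(dtype=float)
    e = velocities["elevation_m"].to_numpy(dtype=float)
    if np.ptp(v) == 0 or np.ptp(e) == 0:
        raise DomainError("zero variance in velocity or elevation")
    r, p = stats.pearsonr(v, e)
    return float(r), float(p)


def compare_ranges_anova(velocities: pd.DataFrame) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of velocity across mountain ranges."""
    groups = [g["velocity"].to_numpy(dtype=float) for _, g in velocities.groupby("region")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DomainError("need >= 2 regions with >= 2 velocities each")
    if all(np.ptp(g) == 0 for g in groups):
        raise DomainError("zero within-group variance in every region")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
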