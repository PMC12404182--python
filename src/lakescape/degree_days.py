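"""Growing and killing degree days from monthly mean air temperatures.

Degree days accumulate the excess of mean temperature over a threshold,
DD = sum_t (T_t - T0) for T_t > T0.  With monthly-resolution input each day
of a month is assigned that month's mean temperature, so a month contributes
``n_days * max(0, tas - T0)`` and a year is the sum over its 12 months.
GDD uses a fixed base (default 0 degC, the parsimonious threshold for fish
growth); KDD uses a region-specific supraoptimal threshold, the 90th
percentile of the region's pooled historical monthly means.  Negative
monthly contributions are truncated to zero (no heat accrued), and
watershed-years with GDD = 0 or KDD = 0 are retained.
"""

from __future__ import annotations

import calendar as _cal
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError, IncompleteYearError

__all__ = [
    "DegreeDayConfig",
    "RegionThreshold",
    "days_in_month",
    "monthly_degree_days",
    "annual_degree_days",
    "kdd_threshold",
    "kdd_thresholds_by_region",
    "compute_degree_day_table",
    "climatology_degree_days",
]

_FIXED_365 = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


@dataclass(frozen=True)
class DegreeDayConfig:
    gdd_base_c: float = 0.0
    kdd_quantile: float = 0.90
    calendar: str = "gregorian"  # or "fixed_365"

    def __post_init__(self) -> None:
        if not 0.0 < self.kdd_quantile < 1.0:
            raise ConfigurationError("kdd_quantile must be in (0, 1)")
        if self.calendar not in ("gregorian", "fixed_365"):
            raise ConfigurationError("calendar must be 'gregorian' or 'fixed_365'")


@dataclass(frozen=True)
class RegionThreshold:
    region: str
    kdd_threshold_c: float
    quantile: float
    n_values: int


def days_in_month(year: int, month: int, calendar: str = "gregorian") -> int:
    """Day count for a month; ``fixed_365`` ignores leap years."""
    if not 1 <= month <= 12:
        raise DomainError(f"month must be in 1..12, got {month}")
    if calendar == "fixed_365":
        return _FIXED_365[month - 1]
    if calendar == "gregorian":
        return _cal.monthrange(int(year), int(month))[1]
    raise ConfigurationError(f"unknown calendar {calendar!r}")


def monthly_degree_days(tas_c: float, base_c: float, n_days: int) -> float:
    """Degree days of one month: ``n_days * max(0, tas_c - base_c)``."""
    if n_days < 1:
        raise DomainError("n_days must be >= 1")
    return n_days * max(0.0, float(tas_c) - float(base_c))


def annual_degree_days(
    monthly: pd.DataFrame, base_c: float, calendar: str = "gregorian"
) -> float:
    """Sum of monthly degree days for one watershed-year.

    ``monthly`` needs columns ``year``, ``month``, ``tas_c`` covering all 12
    months exactly once; partial years raise :class:`IncompleteYearError`
    (mirroring the exclusion of incomplete first-year data rather than
    imputing).
    """
    months = monthly["month"].to_numpy()
    if sorted(months.tolist()) != list(range(1, 13)):
        missing = sorted(set(range(1, 13)) - set(int(m) for m in months))
        raise IncompleteYearError(
            f"need exactly months 1..12, missing/duplicated: {missing or 'duplicates'}"
        )
    total = 0.0
    for _, row in monthly.iterrows():
        n = days_in_month(int(row["year"]), int(row["month"]), calendar)
        total += monthly_degree_days(row["tas_c"], base_c, n)
    return total


def kdd_threshold(
    values, quantile: float = 0.90, region: str = ""
) -> RegionThreshold:
    """Empirical quantile of a region's pooled historical monthly means.

    Uses the linear-interpolation order-statistic convention (position
    h = (n-1)q + 1), so values 1..10 at q = 0.9 give 9.1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("kdd_threshold needs at least one value")
    if not 0.0 < quantile < 1.0:
        raise DomainError("quantile must be in (0, 1)")
    t = float(np.quantile(arr, quantile, method="linear"))
    return RegionThreshold(region, t, quantile, int(arr.size))


def kdd_thresholds_by_region(
    temps: pd.DataFrame, watersheds: pd.DataFrame, quantile: float = 0.90
) -> pd.DataFrame:
    """Per-region KDD thresholds from all pooled (watershed, year, month) means."""
    merged = temps.merge(watersheds[["watershed_id", "region"]], on="watershed_id")
    rows = [
        kdd_threshold(g["tas_c"].to_numpy(), quantile, region)
        for region, g in merged.groupby("region", sort=True)
    ]
    return pd.DataFrame(
        {
            "region": [r.region for r in rows],
            "kdd_threshold_c": [r.kdd_threshold_c for r in rows],
            "quantile": [r.quantile for r in rows],
            "n_values": [r.n_values for r in rows],
        }
    )


def _month_days_vector(years: np.ndarray, months: np.ndarray, calendar: str) -> np.ndarray:
    if calendar == "fixed_365":
        return np.asarray(_FIXED_365)[months - 1]
    leap = np.vectorize(_cal.isleap)(years)
    days = np.asarray(_FIXED_365)[months - 1].copy()
    days[(months == 2) & leap] = 29
    return days


def compute_degree_day_table(
    temps: pd.DataFrame,
    watersheds: pd.DataFrame,
    thresholds: pd.DataFrame,
    cfg: DegreeDayConfig = DegreeDayConfig(),
) -> pd.DataFrame:
    """Annual GDD/KDD per complete watershed-year.

    GDD accumulates above ``cfg.gdd_base_c``; KDD above the watershed's
    region threshold.  Incomplete years are dropped with a warning; rows
    where GDD or KDD is zero are retained.  Columns: ``watershed_id``,
    ``region``, ``year``, ``gdd``, ``kdd``.
    """
    d = temps.merge(watersheds[["watershed_id", "region"]], on="watershed_id")
    missing = set(d["region"]) - set(thresholds["region"])
    if missing:
        raise KeyError(f"no KDD threshold for region(s): {sorted(missing)}")
    d = d.merge(thresholds[["region", "kdd_threshold_c"]], on="region")

    years = d["year"].to_numpy(dtype=int)
    months = d["month"].to_numpy(dtype=int)
    ndays = _month_days_vector(years, months, cfg.calendar)
    tas = d["tas_c"].to_numpy()
    d = d.assign(
        _gdd_m=ndays * np.clip(tas - cfg.gdd_base_c, 0.0, None),
        _kdd_m=ndays * np.clip(tas - d["kdd_threshold_c"].to_numpy(), 0.0, None),
    )
    g = (
        d.groupby(["watershed_id", "region", "year"], sort=True)
        .agg(gdd=("_gdd_m", "sum"), kdd=("_kdd_m", "sum"), _n=("month", "nunique"),
             _rows=("month", "size"))
        .reset_index()
    )
    incomplete = g[(g["_n"] != 12) | (g["_rows"] != 12)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} incomplete watershed-year(s) "
            f"(first: {incomplete.iloc[0]['watershed_id']} "
            f"{int(incomplete.iloc[0]['year'])})",
            stacklevel=2,
        )
        g = g[(g["_n"] == 12) & (g["_rows"] == 12)]
    return g.drop(columns=["_n", "_rows"]).reset_index(drop=True)


def climatology_degree_days(
    climatology: pd.DataFrame,
    watersheds: pd.DataFrame,
    thresholds: pd.DataFrame,
    cfg: DegreeDayConfig = DegreeDayConfig(),
) -> pd.DataFrame:
    """Annual-equivalent GDD/KDD per watershed-period from 12 period-month means.

    A climatology has no specific year, so non-leap (365-day) month lengths
    are used.  Thresholds come from historical data only.  Columns:
    ``watershed_id``, ``region``, ``period``, ``gdd``, ``kdd``.
    """
    d = climatology.merge(watersheds[["watershed_id", "region"]], on="watershed_id")
    missing = set(d["region"]) - set(thresholds["region"])
    if missing:
        raise KeyError(f"no KDD threshold for region(s): {sorted(missing)}")
    d = d.merge(thresholds[["region", "kdd_threshold_c"]], on="region")

    counts = d.groupby(["watershed_id", "period"])["month"].nunique()
    bad = counts[counts != 12]
    if len(bad):
        raise IncompleteYearError(
            f"climatology incomplete for {len(bad)} watershed-period(s), "
            f"first: {bad.index[0]}"
        )
    months = d["month"].to_numpy(dtype=int)
    ndays = np.asarray(_FIXED_365)[months - 1]
    tas = d["tas_c"].to_numpy()
    d = d.assign(
        _gdd_m=ndays * np.clip(tas - cfg.gdd_base_c, 0.0, None),
        _kdd_m=ndays * np.clip(tas - d["kdd_threshold_c"].to_numpy(), 0.0, None),
    )
    return (
        d.groupby(["watershed_id", "region", "period"], sort=True)
        .agg(gdd=("_gdd_m", "sum"), kdd=("_kdd_m", "sum"))
        .reset_index()
    )
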