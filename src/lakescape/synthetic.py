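"""Synthetic mountain-lake landscapes and monthly air-temperature series.

The generator emulates the statistical structure the downstream analysis
assumes: watershed points grouped into mountain-range regions, monthly mean
air temperatures with a seasonal cycle, an elevation lapse, a linear warming
trend whose rate depends on elevation, and i.i.d. Gaussian noise; plus
noise-free period-month climatologies with stepwise warming offsets standing
in for projected scenario data.  Every watershed's true warming slope is
recorded so parameter-recovery tests have a known answer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "LandscapeConfig",
    "ClimateGenParams",
    "generate_landscape",
    "true_slopes",
    "generate_monthly_series",
    "generate_projection_climatology",
]

_PERIOD_SPAN = re.compile(r"^\s*(\d{4})\D+(\d{4})\s*$")


@dataclass(frozen=True)
class LandscapeConfig:
    """Layout of the synthetic landscape.

    ``elevation_bands_m``, when given, splits each region's watersheds as
    evenly as possible across the listed (low, high) elevation bands instead
    of sampling uniformly over ``elevation_range_m`` — used to build
    landscapes with distinct latent thermal tiers.
    ``region_elevation_offsets_m`` adds a per-region offset (one entry per
    region) for regions that sit systematically higher or lower.
    """

    n_regions: int = 2
    watersheds_per_region: int = 50
    elevation_range_m: tuple[float, float] = (200.0, 1800.0)
    seed: int = 0
    elevation_bands_m: Sequence[tuple[float, float]] | None = None
    region_elevation_offsets_m: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if self.watersheds_per_region < 2:
            raise ConfigurationError(
                "watersheds_per_region must be >= 2 (random-slope models need "
                ">= 2 grouping units)"
            )
        lo, hi = self.elevation_range_m
        if not lo < hi:
            raise ConfigurationError("elevation_range_m must satisfy min < max")
        if self.elevation_bands_m is not None:
            for band in self.elevation_bands_m:
                if not band[0] < band[1]:
                    raise ConfigurationError(f"elevation band {band} must satisfy min < max")
        if (
            self.region_elevation_offsets_m is not None
            and len(self.region_elevation_offsets_m) != self.n_regions
        ):
            raise ConfigurationError(
                "region_elevation_offsets_m must have one entry per region"
            )


@dataclass(frozen=True)
class ClimateGenParams:
    """Parameters of the structural temperature model.

    Monthly mean temperature of watershed *w* in year *y*, month *m*:

        T = baseline - lapse * elev_km
            + amplitude * cos(2*pi*(m - peak_month)/12)
            + slope_w * (y - first_year) + eps,   eps ~ N(0, noise_sd^2)

    with the watershed's true warming slope linear in elevation,
    ``slope_w = trend_base + trend_elevation_coupling * elev_km``
    (a negative coupling makes low-elevation watersheds warm fastest).
    Period climatologies are the noise-free structural mean at the period's
    midpoint year plus the period's warming offset.
    """

    baseline_temp_c: float = 14.0
    lapse_rate_c_per_km: float = 6.5
    seasonal_amplitude_c: float = 10.0
    peak_month: int = 7
    trend_base_c_per_yr: float = 0.03
    trend_elevation_coupling: float = -0.015  # degC/yr per km of elevation
    noise_sd_c: float = 0.5
    year_range: tuple[int, int] = (1980, 2019)
    period_offsets_c: Mapping[str, float] = field(
        default_factory=lambda: {"2011-2040": 1.0, "2041-2070": 2.0, "2071-2100": 3.0}
    )
    period_midpoints_yr: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd_c < 0:
            raise ConfigurationError("noise_sd_c must be >= 0")
        if not self.year_range[0] <= self.year_range[1]:
            raise ConfigurationError("year_range must satisfy first <= last")
        if not 1 <= self.peak_month <= 12:
            raise ConfigurationError("peak_month must be in 1..12")

    def period_midpoint(self, period: str) -> float:
        """Midpoint year used to evaluate the warming trend for a period.

        Resolution order: explicit ``period_midpoints_yr`` entry, then a
        label of the form "YYYY-YYYY", then the historical window midpoint
        (which only matters when the trend is nonzero).
        """
        if self.period_midpoints_yr and period in self.period_midpoints_yr:
            return float(self.period_midpoints_yr[period])
        m = _PERIOD_SPAN.match(period)
        if m:
            return (int(m.group(1)) + int(m.group(2))) / 2.0
        return (self.year_range[0] + self.year_range[1]) / 2.0


def generate_landscape(cfg: LandscapeConfig) -> pd.DataFrame:
    """Sample watershed points: id, region label and elevation.

    Returns a frame with columns ``watershed_id``, ``region``,
    ``elevation_m``; deterministic for a given config (seed included).
    """
    rng = np.random.default_rng(cfg.seed)
    records = []
    n = cfg.watersheds_per_region
    for r in range(cfg.n_regions):
        region = f"r{r + 1}"
        offset = (
            cfg.region_elevation_offsets_m[r]
            if cfg.region_elevation_offsets_m is not None
            else 0.0
        )
        if cfg.elevation_bands_m is None:
            elev = rng.uniform(*cfg.elevation_range_m, size=n)
        else:
            bands = cfg.elevation_bands_m
            # round-robin so bands are as even as possible
            idx = np.arange(n) % len(bands)
            elev = np.array([rng.uniform(*bands[i]) for i in idx])
        for j in range(n):
            records.append(
                {
                    "watershed_id": f"{region}_w{j + 1:03d}",
                    "region": region,
                    "elevation_m": float(elev[j] + offset),
                }
            )
    return pd.DataFrame.from_records(records)


def true_slopes(watersheds: pd.DataFrame, params: ClimateGenParams) -> pd.DataFrame:
    """Per-watershed true warming slope (degC/yr), linear in elevation."""
    elev_km = watersheds["elevation_m"].to_numpy() / 1000.0
    slope = params.trend_base_c_per_yr + params.trend_elevation_coupling * elev_km
    return pd.DataFrame(
        {
            "watershed_id": watersheds["watershed_id"].to_numpy(),
            "true_slope_c_per_yr": slope,
            "elevation_m": watersheds["elevation_m"].to_numpy(),
        }
    )


def _structural_mean(
    elev_km: np.ndarray, month: np.ndarray, years_since_start: np.ndarray,
    params: ClimateGenParams,
) -> np.ndarray:
    slope = params.trend_base_c_per_yr + params.trend_elevation_coupling * elev_km
    seasonal = params.seasonal_amplitude_c * np.cos(
        2.0 * np.pi * (month - params.peak_month) / 12.0
    )
    return (
        params.baseline_temp_c
        - params.lapse_rate_c_per_km * elev_km
        + seasonal
        + slope * years_since_start
    )


def generate_monthly_series(
    watersheds: pd.DataFrame, params: ClimateGenParams, seed: int
) -> pd.DataFrame:
    """Monthly mean temperatures for every watershed x year x month.

    Columns: ``watershed_id``, ``year``, ``month``, ``tas_c``.
    """
    if len(watersheds) == 0:
        raise ConfigurationError("watersheds table is empty")
    rng = np.random.default_rng(seed)
    y0, y1 = params.year_range
    years = np.arange(y0, y1 + 1)
    months = np.arange(1, 13)

    n_w = len(watersheds)
    wid = np.repeat(watersheds["watershed_id"].to_numpy(), len(years) * 12)
    elev_km = np.repeat(watersheds["elevation_m"].to_numpy() / 1000.0, len(years) * 12)
    year = np.tile(np.repeat(years, 12), n_w)
    month = np.tile(months, n_w * len(years))

    tas = _structural_mean(elev_km, month, (year - y0).astype(float), params)
    if params.noise_sd_c > 0:
        tas = tas + rng.normal(0.0, params.noise_sd_c, size=tas.shape)
    return pd.DataFrame({"watershed_id": wid, "year": year, "month": month, "tas_c": tas})


def generate_projection_climatology(
    watersheds: pd.DataFrame,
    params: ClimateGenParams,
    periods: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Noise-free period-month climatologies with stepwise warming offsets.

    One row per watershed x period x month; columns ``watershed_id``,
    ``period``, ``month``, ``tas_c``.  Projected scenario data lack
    interannual variance, so no noise is added.
    """
    if len(watersheds) == 0:
        raise ConfigurationError("watersheds table is empty")
    if periods is None:
        periods = list(params.period_offsets_c)
    for p in periods:
        if p not in params.period_offsets_c:
            raise ConfigurationError(f"no warming offset defined for period {p!r}")

    y0 = params.year_range[0]
    months = np.arange(1, 13)
    n_w = len(watersheds)
    frames = []
    for p in periods:
        mid = params.period_midpoint(p)
        wid = np.repeat(watersheds["watershed_id"].to_numpy(), 12)
        elev_km = np.repeat(watersheds["elevation_m"].to_numpy() / 1000.0, 12)
        month = np.tile(months, n_w)
        tas = _structural_mean(
            elev_km, month, np.full(month.shape, mid - y0), params
        ) + params.period_offsets_c[p]
        frames.append(
            pd.DataFrame(
                {"watershed_id": wid, "period": p, "month": month, "tas_c": tas}
            )
        )
    return pd.concat(frames, ignore_index=True)
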