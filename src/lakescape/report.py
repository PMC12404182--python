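"""Summary tables and pipeline orchestration.

Produces the membership table (percentage of watersheds per vulnerability
tier per region and time period, with percent change from the historical
baseline), the KDD-change summary (per-region mean killing degree days,
historical vs end-of-century, and percent increase), and `run_pipeline`,
which chains simulate -> degree days -> velocity -> classify -> project ->
report and writes every artifact plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification as cls
from . import degree_days as ddm
from . import synthetic as syn
from . import velocity as vel
from .exceptions import LakescapeError

__all__ = [
    "membership_table",
    "percent_change",
    "kdd_change_summary",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("lakescape")

_TIERS = cls.TIER_ORDER


def percent_change(historic_pct: float, future_pct: float) -> float:
    """Percent change relative to the historic share; NaN when historic is 0.

    Computed on unrounded percentages — rounding is display-only.
    """
    if historic_pct == 0:
        return float("nan")
    return 100.0 * (future_pct - historic_pct) / historic_pct


def membership_table(
    assignments: pd.DataFrame, historic_period: str
) -> pd.DataFrame:
    """Tier shares per (region | all) x time period, plus change vs historic.

    ``assignments`` needs ``watershed_id``, ``region``, ``time_period``,
    ``tier``.  The pooled "all" row uses count-weighted pooling across
    regions, not the mean of region percentages.  Percentages are kept at
    full precision; round only for display.
    """
    periods = list(dict.fromkeys(assignments["time_period"]))
    if historic_period not in periods:
        raise LakescapeError(f"historic period {historic_period!r} absent from assignments")
    rows = []
    scopes = [("all", assignments)] + [
        (r, g) for r, g in assignments.groupby("region", sort=True)
    ]
    for scope, sub in scopes:
        for period in periods:
            cell = sub[sub["time_period"] == period]
            if len(cell) == 0:
                warnings.warn(f"empty cell ({scope}, {period}); row omitted", stacklevel=2)
                continue
            counts = cell["tier"].value_counts()
            n = len(cell)
            row = {"region": scope, "time_period": period, "n": n}
            for t in _TIERS:
                row[f"pct_{t}"] = 100.0 * counts.get(t, 0) / n
            rows.append(row)
    out = pd.DataFrame(rows)
    hist = out[out["time_period"] == historic_period].set_index("region")
    for t in _TIERS:
        out[f"chg_{t}"] = [
            float("nan")
            if r["time_period"] == historic_period
            else percent_change(hist.loc[r["region"], f"pct_{t}"], r[f"pct_{t}"])
            for _, r in out.iterrows()
        ]
    return out


@dataclass
class KddChangeSummary:
    per_region: pd.DataFrame  # region, kdd_hist, kdd_future, pct_increase
    excluded_regions: list[str]
    min_pct: float
    max_pct: float
    mean_pct: float


def kdd_change_summary(
    dd_hist: pd.DataFrame, dd_future: pd.DataFrame
) -> KddChangeSummary:
    """Per-region mean KDD in two epochs and the percent increase.

    Regions with zero historical mean KDD have no defined percent change;
    they are listed separately and excluded from the cross-region min/max/
    mean.  Both tables need ``region`` and ``kdd`` columns and must cover
    the same watersheds.
    """
    w_h = set(dd_hist["watershed_id"])
    w_f = set(dd_future["watershed_id"])
    if w_h != w_f:
        raise LakescapeError(
            f"epochs cover different watersheds ({len(w_h ^ w_f)} mismatched)"
        )
    h = dd_hist.groupby("region")["kdd"].mean()
    f = dd_future.groupby("region")["kdd"].mean()
    per = pd.DataFrame({"kdd_hist": h, "kdd_future": f}).reset_index()
    per["pct_increase"] = [
        percent_change(a, b) if a > 0 else float("nan")
        for a, b in zip(per["kdd_hist"], per["kdd_future"])
    ]
    excluded = per.loc[per["kdd_hist"] <= 0, "region"].tolist()
    ok = per[per["kdd_hist"] > 0]
    if len(ok):
        mn, mx, mean = (
            float(ok["pct_increase"].min()),
            float(ok["pct_increase"].max()),
            float(ok["pct_increase"].mean()),
        )
    else:
        mn = mx = mean = float("nan")
    return KddChangeSummary(per, excluded, mn, mx, mean)


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs; defaults give the demo landscape."""

    out_dir: str = "lakescape_out"
    seed: int = 0
    landscape: syn.LandscapeConfig = field(default_factory=syn.LandscapeConfig)
    climate: syn.ClimateGenParams = field(default_factory=syn.ClimateGenParams)
    degree_days: ddm.DegreeDayConfig = field(default_factory=ddm.DegreeDayConfig)
    transform: str = "ln_gdd_plus1"
    log_base: str = "e"
    velocity_mode: str = "total"
    restarts: int = 25
    historic_label: str = "1980-2019"

    @classmethod
    def from_dict(cls_, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "landscape" in d:
            ls = dict(d["landscape"])
            for k in ("elevation_range_m",):
                if k in ls:
                    ls[k] = tuple(ls[k])
            if "elevation_bands_m" in ls and ls["elevation_bands_m"] is not None:
                ls["elevation_bands_m"] = [tuple(b) for b in ls["elevation_bands_m"]]
            d["landscape"] = syn.LandscapeConfig(**ls)
        if "climate" in d:
            cl = dict(d["climate"])
            if "year_range" in cl:
                cl["year_range"] = tuple(cl["year_range"])
            d["climate"] = syn.ClimateGenParams(**cl)
        if "degree_days" in d:
            d["degree_days"] = ddm.DegreeDayConfig(**d["degree_days"])
        return cls_(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_echo(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, float) and math.isnan(x):
            return None
        return x

    return clean(d)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis and write the artifact bundle.

    Stages: simulate -> degree-days -> velocity -> classify -> project ->
    report.  Writes all CSVs plus ``manifest.json`` (config echo, seed,
    versions, per-file row counts and checksums) into ``cfg.out_dir``.
    Deterministic for a fixed config+seed.  A stage failure aborts with a
    stage-named error and removes any partial outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    artifacts: dict = {}
    stage = "simulate"

    def write(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        artifacts[name] = df

    try:
        t0 = time.monotonic()
        # --- simulate -----------------------------------------------------
        ls = cfg.landscape
        if ls.seed != cfg.seed:
            ls = syn.LandscapeConfig(**{**asdict(ls), "seed": cfg.seed})
        watersheds = syn.generate_landscape(ls)
        temps = syn.generate_monthly_series(watersheds, cfg.climate, seed=cfg.seed + 1)
        climatology = syn.generate_projection_climatology(watersheds, cfg.climate)
        truth = syn.true_slopes(watersheds, cfg.climate)
        write("watersheds.csv", watersheds)
        write("temps_monthly.csv", temps)
        write("climatology.csv", climatology)
        write("truth.csv", truth[["watershed_id", "true_slope_c_per_yr"]])
        log.info("simulate: %d watersheds, %d monthly rows (%.1fs)",
                 len(watersheds), len(temps), time.monotonic() - t0)

        # --- degree days --------------------------------------------------
        stage = "degree-days"
        t0 = time.monotonic()
        thresholds = ddm.kdd_thresholds_by_region(
            temps, watersheds, cfg.degree_days.kdd_quantile
        )
        dd_hist = ddm.compute_degree_day_table(
            temps, watersheds, thresholds, cfg.degree_days
        )
        dd_proj = ddm.climatology_degree_days(
            climatology, watersheds, thresholds, cfg.degree_days
        )
        write("kdd_thresholds.csv", thresholds)
        dd_all = pd.concat(
            [
                dd_hist.rename(columns={"year": "time_key"}).assign(time_kind="year"),
                dd_proj.rename(columns={"period": "time_key"}).assign(time_kind="period"),
            ],
            ignore_index=True,
        )[["watershed_id", "region", "time_key", "time_kind", "gdd", "kdd"]]
        write("degree_days.csv", dd_all)
        log.info("degree-days: %d rows (%.1fs)", len(dd_all), time.monotonic() - t0)

        # --- velocity -----------------------------------------------------
        stage = "velocity"
        t0 = time.monotonic()
        fits, vel_frames, fit_rows = {}, [], []
        for region, g in dd_hist.groupby("region", sort=True):
            fit = vel.fit_random_slope_model(
                g, transform=cfg.transform, region=region, log_base=cfg.log_base
            )
            fits[region] = fit
            r2m, r2c = vel.pseudo_r2(fit)
            vel_frames.append(
                vel.extract_velocities(fit, watersheds, mode=cfg.velocity_mode)
            )
            fit_rows.append(
                {
                    "region": region,
                    "fixed_intercept": fit.fixed_intercept,
                    "fixed_slope": fit.fixed_slope_per_yr,
                    "var_b0": fit.var_b0,
                    "var_b1": fit.var_b1,
                    "cov_b0b1": fit.cov_b0b1,
                    "sigma2": fit.sigma2,
                    "r2_marginal": r2m,
                    "r2_conditional": r2c,
                    "converged": fit.converged,
                    "boundary": fit.boundary,
                }
            )
        velocities = pd.concat(vel_frames, ignore_index=True)
        write("velocities.csv", velocities)
        write("model_fits.csv", pd.DataFrame(fit_rows))
        anova_f, anova_p = vel.compare_ranges_anova(velocities)
        test_rows = [
            {"region": "all", "statistic": "anova_F", "value": anova_f, "p": anova_p}
        ]
        for region, g in velocities.groupby("region", sort=True):
            r, p = vel.velocity_elevation_correlation(g)
            test_rows.append(
                {"region": region, "statistic": "pearson_r_vs_elevation", "value": r, "p": p}
            )
        write("velocity_tests.csv", pd.DataFrame(test_rows))
        log.info("velocity: %d regions (%.1fs)", len(fits), time.monotonic() - t0)

        # --- classify -----------------------------------------------------
        stage = "classify"
        t0 = time.monotonic()
        means = cls.mean_historical_gdd(dd_hist)
        models = cls.fit_tier_models(means, restarts=cfg.restarts, seed=cfg.seed)
        write(
            "tier_models.csv",
            pd.DataFrame(
                [
                    {
                        "region": r,
                        "center_cold": m.centers[0],
                        "center_transitional": m.centers[1],
                        "center_hot": m.centers[2],
                        "scaler_mean": m.scaler_mean,
                        "scaler_sd": m.scaler_sd,
                        "accuracy": m.accuracy,
                    }
                    for r, m in models.items()
                ]
            ),
        )
        log.info("classify: %d tier models (%.1fs)", len(models), time.monotonic() - t0)

        # --- project ------------------------------------------------------
        stage = "project"
        t0 = time.monotonic()
        frames = []
        for region, m in models.items():
            hist = means[means["region"] == region]
            frames.append(
                cls.predict_membership(
                    m,
                    hist.rename(columns={"mean_gdd": "gdd"}).assign(
                        period=cfg.historic_label
                    ),
                )
            )
            proj = dd_proj[dd_proj["region"] == region]
            frames.append(cls.predict_membership(m, proj))
        assignments = pd.concat(frames, ignore_index=True).merge(
            watersheds[["watershed_id", "region"]], on="watershed_id"
        )[
            ["watershed_id", "region", "time_period", "tier",
             "p_cold", "p_transitional", "p_hot"]
        ]
        write("assignments.csv", assignments)
        log.info("project: %d assignments (%.1fs)", len(assignments), time.monotonic() - t0)

        # --- report -------------------------------------------------------
        stage = "report"
        t0 = time.monotonic()
        membership = membership_table(assignments, cfg.historic_label)
        write("membership_table.csv", membership)
        last_period = list(cfg.climate.period_offsets_c)[-1]
        kdd = kdd_change_summary(
            dd_hist, dd_proj[dd_proj["period"] == last_period]
        )
        kdd_df = kdd.per_region.assign(
            future_period=last_period,
            summary_min=kdd.min_pct, summary_max=kdd.max_pct, summary_mean=kdd.mean_pct,
        )
        write("kdd_change.csv", kdd_df)
        log.info("report: done (%.1fs)", time.monotonic() - t0)

        manifest = {
            "seed": cfg.seed,
            "config": _config_echo(cfg),
            "versions": _versions(),
            "files": {
                p.name: {"rows": len(artifacts[p.name]), "sha256": _sha256(p)}
                for p in written
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        artifacts["manifest"] = manifest
        artifacts["fits"] = fits
        artifacts["models"] = models
        artifacts["kdd_summary"] = kdd
        return artifacts
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise LakescapeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _versions() -> dict:
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "lakescape": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
    }
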