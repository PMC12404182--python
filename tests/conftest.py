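import numpy as np
import pandas as pd
import pytest

from lakescape import (
    ClimateGenParams,
    DegreeDayConfig,
    LandscapeConfig,
    PipelineConfig,
    run_pipeline,
)
from lakescape import degree_days as ddm
from lakescape import synthetic as syn


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """One full default pipeline run (2 regions x 50 watersheds x 40 years,
    3 projection periods), shared across tests."""
    out = tmp_path_factory.mktemp("demo")
    cfg = PipelineConfig(out_dir=str(out), seed=11)
    return cfg, run_pipeline(cfg)


@pytest.fixture(scope="session")
def recovery_landscape():
    """50-watershed single-region landscape with known true slopes and its
    annual degree-day table (noise 0.5 degC)."""
    lcfg = LandscapeConfig(n_regions=1, watersheds_per_region=50, seed=7)
    w = syn.generate_landscape(lcfg)
    params = ClimateGenParams(noise_sd_c=0.5)
    temps = syn.generate_monthly_series(w, params, seed=8)
    truth = syn.true_slopes(w, params)
    thr = ddm.kdd_thresholds_by_region(temps, w)
    dd = ddm.compute_degree_day_table(temps, w, thr, DegreeDayConfig())
    return w, params, temps, truth, dd


def make_panel(seed=42, n_groups=20, n_years=40, beta0=6.0, beta1=0.02,
               sd_b0=0.5, sd_b1=0.01, sigma=0.05):
    """Balanced transformed-scale panel with known mixed-model parameters.

    Returns (dd_table, y, yc, groups_idx): the table stores gdd = expm1(y)
    so that the ln(x+1) transform reproduces y exactly.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(1980, 1980 + n_years, dtype=float)
    yc = years - years.mean()
    b0 = rng.normal(0, sd_b0, n_groups)
    b1 = rng.normal(0, sd_b1, n_groups)
    ys, rows, gidx, eps_all = [], [], [], []
    for i in range(n_groups):
        eps = rng.normal(0, sigma, n_years)
        yi = beta0 + b0[i] + (beta1 + b1[i]) * yc + eps
        ys.append(yi)
        eps_all.append(eps)
        gidx.append(np.arange(i * n_years, (i + 1) * n_years))
        for t in range(n_years):
            rows.append((f"w{i:03d}", years[t], np.expm1(yi[t])))
    dd = pd.DataFrame(rows, columns=["watershed_id", "year", "gdd"])
    truth = dict(
        beta0=beta0, beta1=beta1, b0=b0, b1=b1, eps=np.concatenate(eps_all)
    )
    return dd, np.concatenate(ys), np.tile(yc, n_groups), gidx, truth
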