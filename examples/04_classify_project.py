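"""Vulnerability tiers and their projection onto future climate periods.

Watersheds are clustered into cold / transitional / hot tiers by 1-D k-means
on ln-transformed mean historical GDD; a linear discriminant on the same
standardized feature then scores projected period GDD and returns posterior
tier probabilities for each future period.
"""

from lakescape import (
    ClimateGenParams,
    LandscapeConfig,
    climatology_degree_days,
    compute_degree_day_table,
    fit_tier_models,
    generate_landscape,
    generate_monthly_series,
    generate_projection_climatology,
    kdd_thresholds_by_region,
    mean_historical_gdd,
    predict_membership,
)

watersheds = generate_landscape(LandscapeConfig(n_regions=1, watersheds_per_region=50, seed=9))
params = ClimateGenParams()
temps = generate_monthly_series(watersheds, params, seed=10)
clim = generate_projection_climatology(watersheds, params)
thr = kdd_thresholds_by_region(temps, watersheds)
dd_hist = compute_degree_day_table(temps, watersheds, thr)
dd_proj = climatology_degree_days(clim, watersheds, thr)

means = mean_historical_gdd(dd_hist)
model = fit_tier_models(means, seed=0)["r1"]
print("k-means centers on the ln(GDD+1) scale (cold < transitional < hot):",
      model.centers.round(2))
print(f"discriminant resubstitution accuracy: {model.accuracy:.1%}")
print("\nhistorical tier counts:")
print(model.assignments["tier"].value_counts().to_string())

assign = predict_membership(model, dd_proj)
print("\nprojected tier counts per period (warming pushes watersheds hot-ward):")
print(assign.groupby(["time_period", "tier"]).size().unstack(fill_value=0).to_string())
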