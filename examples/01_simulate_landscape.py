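"""Generate a synthetic mountain-lake landscape and its temperature series.

Builds 2 regions x 5 watersheds, draws 40 years of monthly mean air
temperatures with a seasonal cycle, elevation lapse and elevation-dependent
warming trend, and prints the true warming slopes the series were built from.
"""

from lakescape import (
    ClimateGenParams,
    LandscapeConfig,
    generate_landscape,
    generate_monthly_series,
    generate_projection_climatology,
    true_slopes,
)

cfg = LandscapeConfig(n_regions=2, watersheds_per_region=5, seed=1)
watersheds = generate_landscape(cfg)
params = ClimateGenParams()
temps = generate_monthly_series(watersheds, params, seed=2)
clim = generate_projection_climatology(watersheds, params)
truth = true_slopes(watersheds, params)

print(watersheds.to_string(index=False))
print(f"\n{len(temps)} monthly temperature rows "
      f"({params.year_range[0]}-{params.year_range[1]}), "
      f"{len(clim)} climatology rows over {clim['period'].nunique()} periods")
print("\nTrue warming slope per watershed (degC/yr; lower elevation = faster):")
print(truth.round(4).to_string(index=False))
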